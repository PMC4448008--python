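"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from mirpipe.io import MirnaReference, Placement, SequenceRecord


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def tiny_reference() -> MirnaReference:
    """Two hand-built precursors: perfect 21-bp stems with an 8-nt loop.

    prec1 carries a documented 5p mature; prec2 a documented 3p mature.
    """
    m1 = "TGACAGAAGAGAGTGAGCACA"  # 21 nt, 5'-U
    loop = "CTCACAAC"
    prec1 = m1 + loop + _revcomp(m1)
    m2 = "TTTGGATTGAAGGGAGCTCTA"
    prec2 = _revcomp(m2) + loop + m2
    placements = [
        Placement("syn-miR1-5p", "syn-MIR1", 0, 21, "5p"),
        Placement("syn-miR2-3p", "syn-MIR2", 29, 50, "3p"),
    ]
    return MirnaReference(
        [SequenceRecord("syn-MIR1", prec1), SequenceRecord("syn-MIR2", prec2)],
        [SequenceRecord("syn-miR1-5p", m1), SequenceRecord("syn-miR2-3p", m2)],
        placements,
    )


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]
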