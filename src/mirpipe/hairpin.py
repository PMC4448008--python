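"""Evaluation of candidate pre-miRNA hairpins against 11 structural criteria.

A candidate window is folded, the stem-loop component containing the
candidate mature is isolated, and eleven measurements are taken: largest
stem bulge, total stem pairs, folding energy, hairpin extent, terminal
loop length, and six bookkeeping rules over the mature region (bulge
sizes, biased bulges/errors, unpaired "errors", pairs, and the fraction of
the mature inside the stem). "Biased" means all unpaired nucleotides of a
bulge lie on one strand of the duplex. Windows whose mature-bearing
component contains more than one terminal loop are rejected outright as
"not a hairpin"; incidental stem-loops elsewhere in the window (flanking
genomic sequence folds too) are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .fold import (
    HAIRPIN_PENALTY,
    INTERIOR_BASE,
    INTERIOR_PER_NT,
    PrecursorFold,
    _ENC,
    _STRENGTH,
    pair_table,
)

__all__ = ["HairpinCriteria", "HairpinEvaluation", "evaluate_hairpin", "CRITERIA_ORDER"]

CRITERIA_ORDER = (
    "max_stem_bulge",
    "stem_pairs",
    "energy",
    "hairpin_len",
    "loop_len",
    "max_mature_bulge",
    "max_biased_errors_in_bulge",
    "biased_bulges_mature",
    "mature_errors",
    "mature_pairs",
    "pct_mature_in_stem",
)


@dataclass(frozen=True)
class HairpinCriteria:
    """Thresholds for the 11 hairpin criteria (defaults are the pipeline's)."""

    max_bulge_stem: int = 12
    min_stem_pairs: int = 16
    energy_cutoff: float = -15.0  # kcal/mol, folding free energy must be <= this
    min_hairpin_len: int = 50
    max_loop_len: int = 200
    max_bulge_mature: int = 4
    max_biased_errors_one_bulge_mature: int = 2
    max_biased_bulges_mature: int = 2
    max_errors_mature: int = 4
    min_mature_pairs: int = 12
    min_pct_mature_in_stem: float = 80.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v != v or v in (float("inf"), float("-inf")):
                raise ValueError(f"criterion threshold {f.name} must be finite")


@dataclass
class HairpinEvaluation:
    """Measured values and verdicts for the 11 criteria of one candidate."""

    is_hairpin: bool
    values: dict[str, float | None] = field(default_factory=dict)
    verdicts: dict[str, bool] = field(default_factory=dict)
    reason: str | None = None

    @property
    def overall(self) -> bool:
        return self.is_hairpin and all(self.verdicts.get(k, False) for k in CRITERIA_ORDER)

    def failed(self) -> list[str]:
        if not self.is_hairpin:
            return list(CRITERIA_ORDER)
        return [k for k in CRITERIA_ORDER if not self.verdicts.get(k, False)]


def _not_hairpin(reason: str) -> HairpinEvaluation:
    return HairpinEvaluation(
        is_hairpin=False,
        values={k: None for k in CRITERIA_ORDER},
        verdicts={k: False for k in CRITERIA_ORDER},
        reason=reason,
    )


def _component_energy(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Re-score one stem-loop component under the shipped energy model."""
    x = [_ENC[c] for c in seq]
    e = HAIRPIN_PENALTY
    for (i, j), (ii, jj) in zip(pairs, pairs[1:]):
        di, dj = ii - i - 1, j - jj - 1
        if di == 0 and dj == 0:
            e += -(_STRENGTH[x[i], x[j]] + _STRENGTH[x[ii], x[jj]])
        else:
            e += INTERIOR_BASE + INTERIOR_PER_NT * (di + dj)
    return round(e, 2)


def evaluate_hairpin(
    pf: PrecursorFold,
    criteria: HairpinCriteria = HairpinCriteria(),
    use_stated_energy: bool = False,
) -> HairpinEvaluation:
    """Measure the 11 criteria for the mature-bearing stem-loop of *pf*.

    ``pf.mature_span`` must be set. With *use_stated_energy* the fold's own
    energy value (e.g. from an external structure file) feeds criterion 3;
    otherwise the mature's component is re-scored under the shipped model
    so that unrelated stem-loops in the window do not contribute.
    """
    if pf.mature_span is None:
        raise ValueError("mature_span must be set before evaluation")
    ms, me = pf.mature_span
    pt = pair_table(pf.structure)
    n = len(pf.structure)

    # top-level components: outermost pairs not enclosed by any other pair
    components: list[tuple[int, int]] = []
    i = 0
    while i < n:
        j = pt[i]
        if j > i:
            components.append((i, j))
            i = j + 1
        else:
            i += 1
    # component with the greatest mature overlap
    best, best_ov = None, 0
    for a, b in components:
        ov = max(0, min(me, b + 1) - max(ms, a))
        if ov > best_ov:
            best, best_ov = (a, b), ov
    if best is None:
        return _not_hairpin("mature not contained in any paired component")
    a0, b0 = best

    pairs = [(i, pt[i]) for i in range(a0, b0 + 1) if pt[i] > i]
    # single terminal loop <=> pairs are strictly nested
    pairs.sort()
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i1 < i2 and j2 < j1):
            return _not_hairpin("multiloop: more than one terminal loop")

    inner_i, inner_j = pairs[-1]
    loop_len = inner_j - inner_i - 1
    stem_pairs = len(pairs)
    extent = b0 - a0 + 1
    energy = pf.energy if use_stated_energy else _component_energy(pf.seq, pairs)

    # bulge events along the helix walk
    max_stem_bulge = 0
    mature_bulge_sizes: list[int] = []
    biased_bulge_errors: list[int] = []
    n_biased_mature = 0
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        di, dj = i2 - i1 - 1, j1 - j2 - 1
        if di + dj == 0:
            continue
        size = di + dj
        max_stem_bulge = max(max_stem_bulge, size)
        left = range(i1 + 1, i2)
        right = range(j2 + 1, j1)
        in_mature = [p for p in list(left) + list(right) if ms <= p < me]
        if not in_mature:
            continue
        mature_bulge_sizes.append(size)
        biased = (di > 0) != (dj > 0)
        if biased:
            n_biased_mature += 1
            biased_bulge_errors.append(len(in_mature))

    in_loop = sum(1 for p in range(ms, me) if inner_i < p < inner_j)
    in_stem = sum(1 for p in range(ms, me) if a0 <= p <= b0) - in_loop
    mature_pairs = sum(1 for p in range(ms, me) if pt[p] >= 0)
    mature_errors = in_stem - sum(
        1 for p in range(ms, me) if pt[p] >= 0 and a0 <= p <= b0
    )
    pct_in_stem = 100.0 * in_stem / (me - ms)

    values: dict[str, float | None] = {
        "max_stem_bulge": max_stem_bulge,
        "stem_pairs": stem_pairs,
        "energy": energy,
        "hairpin_len": extent,
        "loop_len": loop_len,
        "max_mature_bulge": max(mature_bulge_sizes) if mature_bulge_sizes else 0,
        "max_biased_errors_in_bulge": max(biased_bulge_errors) if biased_bulge_errors else 0,
        "biased_bulges_mature": n_biased_mature,
        "mature_errors": mature_errors,
        "mature_pairs": mature_pairs,
        "pct_mature_in_stem": round(pct_in_stem, 2),
    }
    c = criteria
    verdicts = {
        "max_stem_bulge": values["max_stem_bulge"] <= c.max_bulge_stem,
        "stem_pairs": values["stem_pairs"] >= c.min_stem_pairs,
        "energy": values["energy"] <= c.energy_cutoff,
        "hairpin_len": values["hairpin_len"] >= c.min_hairpin_len,
        "loop_len": values["loop_len"] <= c.max_loop_len,
        "max_mature_bulge": values["max_mature_bulge"] <= c.max_bulge_mature,
        "max_biased_errors_in_bulge": values["max_biased_errors_in_bulge"]
        <= c.max_biased_errors_one_bulge_mature,
        "biased_bulges_mature": values["biased_bulges_mature"] <= c.max_biased_bulges_mature,
        "mature_errors": values["mature_errors"] <= c.max_errors_mature,
        "mature_pairs": values["mature_pairs"] >= c.min_mature_pairs,
        "pct_mature_in_stem": values["pct_mature_in_stem"] >= c.min_pct_mature_in_stem,
    }
    return HairpinEvaluation(is_hairpin=True, values=values, verdicts=verdicts)
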