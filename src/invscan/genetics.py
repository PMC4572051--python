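"""Crossover parsimony on phase-unknown F2 genotypes.

An F2 individual carries two haplotypes whose phase is unobserved. Each
genotype code constrains the ordered haplotype-allele pair at that marker:

    A  -> {(a,a)}                homozygous for the first parent's allele
    B  -> {(b,b)}                homozygous for the other parent's allele
    H  -> {(a,b), (b,a)}         heterozygous
    AH -> {(a,a), (a,b), (b,a)}  dominant scoring: A or H, never B
    -  -> all four               missing

The minimum number of meiotic crossovers needed to explain a genotype vector
under a given marker order is the cheapest path through these state sets,
where the step cost between adjacent markers is the number of haplotype
positions that switch allele. Comparing candidate marker orders by their
total minimum crossover count is the parsimony argument for an inversion:
a genuine segment reversal makes apparent double recombinants vanish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = "-"

#: ordered haplotype states: 0=(a,a), 1=(a,b), 2=(b,a), 3=(b,b)
_STATES = ((0, 0), (0, 1), (1, 0), (1, 1))
CODE_STATES: dict[str, tuple[int, ...]] = {
    "A": (0,),
    "H": (1, 2),
    "B": (3,),
    "AH": (0, 1, 2),
    MISSING: (0, 1, 2, 3),
}
#: crossover cost between states s and t (haplotype positions that switch)
_COST = tuple(
    tuple((a1 != b1) + (a2 != b2) for (b1, b2) in _STATES) for (a1, a2) in _STATES
)


@dataclass
class Marker:
    """A genetic marker with physical and (optional) map coordinates."""

    name: str
    ref_pos_bp: int = 0
    map_pos_cM: float | None = None
    assay: str = "codominant"

    def __post_init__(self) -> None:
        if self.ref_pos_bp < 0:
            raise ValueError("ref_pos_bp must be >= 0")
        if self.assay not in ("codominant", "dominant"):
            raise ValueError("assay must be 'codominant' or 'dominant'")


@dataclass
class GenotypeTable:
    """Individuals x ordered markers, codes in {A, H, B, AH, -}."""

    markers: list[Marker]
    calls: pd.DataFrame  # index = individual ids, columns = marker names

    def __post_init__(self) -> None:
        names = [mk.name for mk in self.markers]
        if list(self.calls.columns) != names:
            raise ValueError("call matrix columns must match the declared marker order")
        bad = set(np.unique(self.calls.to_numpy(dtype=object))) - set(CODE_STATES)
        if bad:
            raise ValueError(f"unknown genotype codes: {sorted(bad)}")

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.index)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, name: str) -> int:
        for i, mk in enumerate(self.markers):
            if mk.name == name:
                return i
        raise KeyError(f"unknown marker {name!r}")


@dataclass(frozen=True)
class MarkerOrder:
    """A candidate permutation of marker indices."""

    permutation: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if sorted(self.permutation) != list(range(len(self.permutation))):
            raise ValueError("not a permutation")

    @staticmethod
    def reference(m: int) -> "MarkerOrder":
        return MarkerOrder(tuple(range(m)), label="reference")

    @staticmethod
    def segment_reversal(m: int, i: int, j: int) -> "MarkerOrder":
        """Reverse the contiguous marker segment [i, j] (inclusive)."""
        perm = list(range(m))
        perm[i : j + 1] = perm[i : j + 1][::-1]
        return MarkerOrder(tuple(perm), label=f"rev[{i}-{j}]")


@dataclass
class ParsimonyResult:
    order: MarkerOrder
    total_crossovers: int
    per_individual: list[int] = field(default_factory=list)


def min_crossovers(genotypes: list[str], order: MarkerOrder | None = None) -> int:
    """Exact minimum crossovers explaining one genotype vector.

    Dynamic programme over the four ordered haplotype-pair states in the
    given marker order (reference order if none).
    """
    codes = list(genotypes)
    if order is not None:
        if len(order.permutation) != len(codes):
            raise ValueError("order length must match genotype vector length")
        codes = [codes[i] for i in order.permutation]
    for c in codes:
        if c not in CODE_STATES:
            raise ValueError(f"unknown genotype code {c!r}")
    if not codes:
        return 0
    INF = 10 ** 9
    prev = [0 if s in CODE_STATES[codes[0]] else INF for s in range(4)]
    for c in codes[1:]:
        allowed = CODE_STATES[c]
        cur = [INF] * 4
        for t in allowed:
            cur[t] = min(prev[s] + _COST[s][t] for s in range(4))
        prev = cur
    return min(prev)


def order_parsimony(table: GenotypeTable, order: MarkerOrder) -> ParsimonyResult:
    """Total and per-individual minimum crossovers under a marker order."""
    mat = table.calls.to_numpy(dtype=object)
    per = [min_crossovers(list(row), order) for row in mat]
    return ParsimonyResult(order=order, total_crossovers=int(sum(per)), per_individual=per)


def best_order(
    table: GenotypeTable, exhaustive: bool | None = None
) -> list[ParsimonyResult]:
    """Rank candidate marker orders by total minimum crossovers.

    Candidates are the reference order plus every contiguous-segment reversal
    (the inversion hypothesis class). With ``exhaustive=True`` (allowed only
    for <= 7 markers) all permutations are searched instead. Ties are broken
    by: reference order first, then smaller reversed segment, then
    lexicographic permutation.
    """
    m = table.n_markers
    if m < 2:
        raise ValueError("need at least 2 markers")
    candidates: list[tuple[MarkerOrder, int]] = [(MarkerOrder.reference(m), 0)]
    if exhaustive:
        if m > 7:
            raise ValueError("exhaustive search limited to 7 markers")
        import itertools

        for perm in itertools.permutations(range(m)):
            if perm == tuple(range(m)):
                continue
            candidates.append((MarkerOrder(perm, label="perm" + str(perm)), m + 1))
    else:
        for i in range(m):
            for j in range(i + 1, m):
                candidates.append((MarkerOrder.segment_reversal(m, i, j), j - i + 1))

    results = []
    for order, seg in candidates:
        res = order_parsimony(table, order)
        is_ref = order.permutation == tuple(range(m))
        results.append((res.total_crossovers, 0 if is_ref else 1, seg, order.permutation, res))
    results.sort(key=lambda r: r[:4])
    return [r[4] for r in results]


def haldane_cM(r: float) -> float:
    """Haldane map distance (cM) from a per-gamete recombination fraction."""
    if r < 0:
        raise ValueError("recombination fraction must be >= 0")
    if r >= 0.5:
        return math.inf
    return -50.0 * math.log(1.0 - 2.0 * r)


def haldane_r(cM: float) -> float:
    """Per-gamete recombination fraction from a Haldane map distance."""
    return 0.5 * (1.0 - math.exp(-2.0 * cM / 100.0))


def recombination_fraction(table: GenotypeTable, marker_a: str, marker_b: str) -> dict:
    """Two-point recombination estimate between two markers.

    An individual is recombinant iff its pairwise minimum crossover count over
    just the two markers is > 0, so dominant (AH) ambiguity resolves
    conservatively to the non-recombinant phase. Individuals with a missing
    call at either marker are non-informative. ``r_per_gamete`` is the total
    pairwise minimum crossover count over 2 x n_informative gametes.
    """
    ia, ib = table.marker_index(marker_a), table.marker_index(marker_b)
    col_a = table.calls.iloc[:, ia].to_numpy(dtype=object)
    col_b = table.calls.iloc[:, ib].to_numpy(dtype=object)
    n_rec = 0
    n_inf = 0
    total_cx = 0
    for ca, cb in zip(col_a, col_b):
        if ca == MISSING or cb == MISSING:
            continue
        n_inf += 1
        cx = min_crossovers([ca, cb])
        total_cx += cx
        if cx > 0:
            n_rec += 1
    r = total_cx / (2 * n_inf) if n_inf else 0.0
    return {
        "n_recombinant_individuals": n_rec,
        "n_crossover_events_min": total_cx,
        "n_informative": n_inf,
        "r_per_gamete": r,
        "cM_haldane": haldane_cM(r),
        "unbounded": r >= 0.5,
    }


def detect_suppression(
    table: GenotypeTable,
    marker_pairs: list[tuple[str, str]],
    physical_bp: list[int],
    genomewide_cM_per_Mbp: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag marker pairs whose recombination is suppressed.

    A pair is flagged iff zero recombinants were observed while the expected
    map length (physical distance x genome-wide cM/Mbp, converted to a
    per-gamete fraction via Haldane) makes zero recombinants among the
    2n informative gametes improbable: (1 - r)^(2n) < alpha.
    """
    if len(marker_pairs) != len(physical_bp):
        raise ValueError("marker_pairs and physical_bp must align")
    rows = []
    for (ma, mb), bp in zip(marker_pairs, physical_bp):
        rf = recombination_fraction(table, ma, mb)
        exp_cM = bp / 1e6 * genomewide_cM_per_Mbp
        r_exp = haldane_r(exp_cM)
        n_gametes = 2 * rf["n_informative"]
        p_zero = (1.0 - r_exp) ** n_gametes
        rows.append(
            {
                "marker_a": ma,
                "marker_b": mb,
                "physical_bp": bp,
                "n_informative": rf["n_informative"],
                "n_recombinant": rf["n_recombinant_individuals"],
                "expected_cM": exp_cM,
                "p_zero_given_expected": p_zero,
                "suppressed": rf["n_recombinant_individuals"] == 0 and p_zero < alpha,
            }
        )
    return pd.DataFrame(rows)
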