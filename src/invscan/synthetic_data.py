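"""Synthetic genome pairs, draft fragmentations, introgression lines and crosses.

This module manufactures the full study system for the pipeline with known
ground truth: a reference region, a diverged wild-relative genome carrying a
large inversion flanked by inverted repeat cassettes (emulating the NB-LRR
repeats that flank real resistance-gene inversions), a draft-style
fragmentation of the wild genome into shuffled/flipped scaffolds, an
introgression line carrying the wild segment in a reference background, and
F2/F_n progenies simulated under a Haldane (no-interference) crossover model
with optional recombination suppression in inversion heterozygotes.

Every operation takes an explicit seed and is byte-deterministic for a fixed
seed and configuration.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import GenotypeTable, Marker
from .records import SequenceRecord, decode, revcomp_codes

_MAX_RATE = 0.2  # guard against degenerate divergence


# ---------------------------------------------------------------------------
# specs and ground truth
# ---------------------------------------------------------------------------


@dataclass
class InversionSpec:
    """An inversion on the reference: [start, end) is reverse-complemented in
    the wild genome, with inverted repeat cassettes of ``cassette_len`` bp
    inserted at both flanks (``cassette_identity`` = fraction of identical
    bases between the two cassette copies)."""

    start: int
    end: int
    cassette_len: int = 0
    cassette_identity: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.start <= self.end:
            raise ValueError("require 0 <= start <= end")
        if self.cassette_len < 0:
            raise ValueError("cassette_len must be >= 0")
        if not 0.0 <= self.cassette_identity <= 1.0:
            raise ValueError("cassette_identity must be in [0, 1]")
        if self.end > self.start:
            if self.end - self.start <= 2 * self.cassette_len:
                raise ValueError("inversion must be longer than both cassettes")
        elif self.cassette_len != 0:
            raise ValueError("empty inversion cannot carry cassettes")

    @property
    def length(self) -> int:
        return self.end - self.start


class RefToWild:
    """Piecewise-linear map from reference to wild coordinates.

    Maintained as copied pieces ``(ref_start, ref_end, wild_start)``;
    positions inside a deleted reference interval map to the wild position of
    the following piece. Insertions into the wild sequence are registered with
    :meth:`insert` (anchored at a reference position)."""

    def __init__(self, pieces: list[tuple[int, int, int]], ref_len: int, wild_len: int):
        self._pieces = sorted(pieces)
        self.ref_len = ref_len
        self.wild_len = wild_len

    def __call__(self, pos: int) -> int:
        if not 0 <= pos <= self.ref_len:
            raise ValueError(f"position {pos} outside reference [0, {self.ref_len}]")
        if pos == self.ref_len:
            return self.wild_len
        starts = [p[0] for p in self._pieces]
        i = bisect.bisect_right(starts, pos) - 1
        if i < 0:
            return 0
        rs, re, ws = self._pieces[i]
        if pos < re:
            return ws + (pos - rs)
        # inside a deleted interval: snap to the next retained base
        if i + 1 < len(self._pieces):
            return self._pieces[i + 1][2]
        return self.wild_len

    def insert(self, ref_anchor: int, length: int) -> None:
        """Register ``length`` wild-only bases inserted before reference
        position ``ref_anchor`` (positions >= ref_anchor shift right)."""
        new: list[tuple[int, int, int]] = []
        for rs, re, ws in self._pieces:
            if re <= ref_anchor:
                new.append((rs, re, ws))
            elif rs >= ref_anchor:
                new.append((rs, re, ws + length))
            else:  # split the piece containing the anchor
                new.append((rs, ref_anchor, ws))
                new.append((ref_anchor, re, ws + (ref_anchor - rs) + length))
        self._pieces = new
        self.wild_len += length


@dataclass
class GenomePairTruth:
    """Ground-truth ledger for a synthetic reference/wild genome pair."""

    inversion: InversionSpec | None
    snp_rate: float
    indel_rate: float
    ref_breakpoints: tuple[int, int] | None
    wild_breakpoints: tuple[int, int] | None
    wild_cassettes: list[tuple[int, int]] = field(default_factory=list)
    n_gap_runs: int = 0
    ref_length: int = 0
    wild_length: int = 0
    scaffold_truth: list[dict] = field(default_factory=list)
    scaffold_gaps: list[tuple[str, str, int]] = field(default_factory=list)
    introgression_segment: tuple[int, int] | None = None
    introgression_junctions: tuple[int, int] | None = None
    ref_to_wild: RefToWild | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Scalar truth values as a two-column key/value table."""
        rows: list[tuple[str, object]] = [
            ("ref_length", self.ref_length),
            ("wild_length", self.wild_length),
            ("snp_rate", self.snp_rate),
            ("indel_rate", self.indel_rate),
            ("n_gap_runs", self.n_gap_runs),
        ]
        if self.inversion is not None and self.inversion.length > 0:
            rows += [
                ("inversion_ref_start", self.ref_breakpoints[0]),
                ("inversion_ref_end", self.ref_breakpoints[1]),
                ("inversion_wild_start", self.wild_breakpoints[0]),
                ("inversion_wild_end", self.wild_breakpoints[1]),
                ("cassette_len", self.inversion.cassette_len),
            ]
        for i, (left, right, gap) in enumerate(self.scaffold_gaps):
            rows.append((f"gap_{left}_{right}", gap))
        if self.introgression_segment is not None:
            rows += [
                ("introgression_ref_start", self.introgression_segment[0]),
                ("introgression_ref_end", self.introgression_segment[1]),
                ("introgression_junction_left", self.introgression_junctions[0]),
                ("introgression_junction_right", self.introgression_junctions[1]),
            ]
        return pd.DataFrame(rows, columns=["key", "value"])


# ---------------------------------------------------------------------------
# genome pair generation
# ---------------------------------------------------------------------------


def generate_reference(
    length: int, gc: float = 0.36, seed: int = 0, id: str = "ref_region", build_tag: str = "refA"
) -> SequenceRecord:
    """Random reference region with the requested GC content.

    The default GC of 0.36 reflects the AT-rich euchromatin typical of
    Solanaceae genome regions.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return SequenceRecord(id=id, seq=decode(codes), build_tag=build_tag)


def _mutate_copy(codes: np.ndarray, identity: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    n_mut = int(round((1.0 - identity) * out.size))
    if n_mut:
        pos = rng.choice(out.size, size=n_mut, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, size=n_mut)) % 4
    return out


def derive_wild_genome(
    ref: SequenceRecord,
    snp_rate: float = 0.02,
    indel_rate: float = 0.001,
    inversion: InversionSpec | None = None,
    n_gap_runs: int = 0,
    seed: int = 0,
    indel_max_len: int = 5,
    gap_run_len: tuple[int, int] = (200, 2000),
) -> tuple[SequenceRecord, GenomePairTruth]:
    """Derive a diverged wild-relative genome from the reference.

    Applied in order: substitutions at ``snp_rate``, short indels (1 to
    ``indel_max_len`` bp, insertion/deletion equiprobable) at ``indel_rate``,
    reverse-complementation of the inversion segment, insertion of inverted
    repeat cassettes at both inversion flanks, and ``n_gap_runs`` runs of N
    (emulating draft-assembly gaps). The returned truth ledger records the
    realized breakpoints after indel shifting and carries the full
    reference-to-wild coordinate map.
    """
    for name, rate in (("snp_rate", snp_rate), ("indel_rate", indel_rate)):
        if not 0.0 <= rate <= _MAX_RATE:
            raise ValueError(f"{name} must be in [0, {_MAX_RATE}]")
    L = len(ref)
    if inversion is not None and inversion.end > L:
        raise ValueError("inversion outside reference bounds")

    rng = np.random.default_rng(seed)
    codes = ref.codes.copy()
    not_n = codes < 4

    # substitutions (always to a different base)
    snp_pos = np.flatnonzero((rng.random(L) < snp_rate) & not_n)
    if snp_pos.size:
        codes[snp_pos] = (codes[snp_pos] + rng.integers(1, 4, size=snp_pos.size)) % 4

    # indels
    ev_pos = np.flatnonzero(rng.random(L) < indel_rate)
    ev_ins = rng.random(ev_pos.size) < 0.5
    ev_len = rng.integers(1, indel_max_len + 1, size=ev_pos.size)
    parts: list[np.ndarray] = []
    pieces: list[tuple[int, int, int]] = []
    cur_ref = 0
    cur_wild = 0
    for pos, is_ins, ln in zip(ev_pos.tolist(), ev_ins.tolist(), ev_len.tolist()):
        if pos < cur_ref:  # swallowed by a previous deletion
            continue
        if pos > cur_ref:
            seg = codes[cur_ref:pos]
            parts.append(seg)
            pieces.append((cur_ref, pos, cur_wild))
            cur_wild += seg.size
            cur_ref = pos
        if is_ins:
            ins = rng.integers(0, 4, size=ln).astype(np.uint8)
            parts.append(ins)
            cur_wild += ln
        else:
            cur_ref = min(pos + int(ln), L)
    if cur_ref < L:
        seg = codes[cur_ref:]
        parts.append(seg)
        pieces.append((cur_ref, L, cur_wild))
        cur_wild += seg.size
    wild = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
    rmap = RefToWild(pieces, ref_len=L, wild_len=wild.size)

    # inversion + flanking cassettes
    cassettes: list[tuple[int, int]] = []
    if inversion is not None and inversion.length > 0:
        ws, we = rmap(inversion.start), rmap(inversion.end)
        wild[ws:we] = revcomp_codes(wild[ws:we])
        cl = inversion.cassette_len
        if cl > 0:
            cas = rng.integers(0, 4, size=cl).astype(np.uint8)
            cas_rc = _mutate_copy(revcomp_codes(cas), inversion.cassette_identity, rng)
            wild = np.concatenate([wild[:ws], cas, wild[ws:]])
            rmap.insert(inversion.start, cl)
            core_end = rmap(inversion.end)  # right cassette goes after the core
            wild = np.concatenate([wild[:core_end], cas_rc, wild[core_end:]])
            rmap.insert(inversion.end, cl)

    # N gap runs (placed away from the inversion and the sequence ends)
    margin = 5000
    lo_blocked = inversion.start - margin if inversion and inversion.length else None
    hi_blocked = inversion.end + margin if inversion and inversion.length else None
    for _ in range(n_gap_runs):
        ln = int(rng.integers(gap_run_len[0], gap_run_len[1] + 1))
        for _attempt in range(100):
            anchor = int(rng.integers(1000, max(1001, L - 1000)))
            if lo_blocked is None or not (lo_blocked <= anchor <= hi_blocked):
                break
        w = rmap(anchor)
        wild = np.concatenate([wild[:w], np.full(ln, 4, dtype=np.uint8), wild[w:]])
        rmap.insert(anchor, ln)

    if inversion is not None and inversion.length > 0:
        cl = inversion.cassette_len
        wb = (rmap(inversion.start), rmap(inversion.end) - cl)
        cassettes = (
            [(wb[0] - cl, wb[0]), (wb[1], wb[1] + cl)] if cl else []
        )
        ref_bp = (inversion.start, inversion.end)
    else:
        wb = None
        ref_bp = None

    truth = GenomePairTruth(
        inversion=inversion,
        snp_rate=snp_rate,
        indel_rate=indel_rate,
        ref_breakpoints=ref_bp,
        wild_breakpoints=wb,
        wild_cassettes=cassettes,
        n_gap_runs=n_gap_runs,
        ref_length=L,
        wild_length=int(wild.size),
        ref_to_wild=rmap,
    )
    rec = SequenceRecord(id=ref.id + "_wild", seq=decode(wild), build_tag="wildA")
    return rec, truth


# ---------------------------------------------------------------------------
# draft fragmentation
# ---------------------------------------------------------------------------


def fragment_scaffolds(
    wild: SequenceRecord,
    break_positions: list[int],
    gap_sizes: list[int],
    shuffle_seed: int = 0,
    truth: GenomePairTruth | None = None,
) -> tuple[list[SequenceRecord], list[dict]]:
    """Fragment the wild genome into draft-style scaffolds.

    At each break position the following ``gap_size`` bases are deleted (the
    unsequenced gap); the resulting scaffolds are returned in shuffled order
    with random strand flips, as a draft assembler would emit them. The truth
    list records, in true genomic order, each scaffold's span on the wild
    genome, the orientation in which it was emitted, and the true gap to the
    next scaffold.
    """
    if len(break_positions) != len(gap_sizes):
        raise ValueError("break_positions and gap_sizes must have equal length")
    L = len(wild)
    prev_end = 0
    for b, g in zip(break_positions, gap_sizes):
        if b <= prev_end or b >= L:
            raise ValueError("break positions must be strictly increasing, inside the sequence, and non-overlapping")
        if g < 0:
            raise ValueError("gap sizes must be >= 0")
        prev_end = b + g
    if prev_end >= L:
        raise ValueError("final gap extends past the sequence end")

    starts = [0] + [b + g for b, g in zip(break_positions, gap_sizes)]
    ends = list(break_positions) + [L]
    n = len(starts)
    rng = np.random.default_rng(shuffle_seed)
    perm = rng.permutation(n)
    flips = rng.integers(0, 2, size=n).astype(bool)

    truth_rows: list[dict] = []
    records: dict[int, SequenceRecord] = {}
    for i, (s, e) in enumerate(zip(starts, ends)):
        sid = f"scf{i + 1:03d}"
        seq = wild.seq[s:e]
        rec = SequenceRecord(id=sid, seq=seq, origin_offset=s, build_tag=wild.build_tag)
        if flips[i]:
            rec = SequenceRecord(id=sid, seq=rec.reverse_complement().seq, origin_offset=s, build_tag=wild.build_tag)
        records[i] = rec
        truth_rows.append(
            {
                "id": sid,
                "true_order": i,
                "wild_start": s,
                "wild_end": e,
                "orientation": "-" if flips[i] else "+",
                "gap_after": gap_sizes[i] if i < n - 1 else None,
            }
        )
    if truth is not None:
        truth.scaffold_truth = truth_rows
        truth.scaffold_gaps = [
            (truth_rows[i]["id"], truth_rows[i + 1]["id"], gap_sizes[i]) for i in range(n - 1)
        ]
    return [records[i] for i in perm], truth_rows


def make_introgression_line(
    ref: SequenceRecord,
    wild: SequenceRecord,
    segment_on_ref: tuple[int, int],
    truth: GenomePairTruth,
) -> tuple[SequenceRecord, tuple[int, int]]:
    """Substitute the wild-homologous segment into the reference background.

    ``segment_on_ref`` is given in reference coordinates; the homologous wild
    span is looked up through the truth coordinate map. A segment that
    partially overlaps the inversion is rejected (the homologous wild region
    would not be contiguous). Returns the introgression-line record and the
    two recombinant junction coordinates on the new sequence.
    """
    s, e = segment_on_ref
    if not 0 <= s <= e <= len(ref):
        raise ValueError("segment outside reference bounds")
    inv = truth.inversion
    if inv is not None and inv.length > 0:
        overlaps = s < inv.end and e > inv.start
        contains = s <= inv.start and e >= inv.end
        if overlaps and not contains:
            raise ValueError("segment partially overlaps the inversion; homology is not contiguous")
    if s == e:
        return (
            SequenceRecord(id=ref.id + "_introgression", seq=ref.seq, build_tag="introgression"),
            (s, s),
        )
    rmap = truth.ref_to_wild
    ws, we = rmap(s), rmap(e)
    seq = ref.seq[:s] + wild.seq[ws:we] + ref.seq[e:]
    junctions = (s, s + (we - ws))
    truth.introgression_segment = (s, e)
    truth.introgression_junctions = junctions
    rec = SequenceRecord(id=ref.id + "_introgression", seq=seq, build_tag="introgression")
    return rec, junctions


# ---------------------------------------------------------------------------
# cross simulation
# ---------------------------------------------------------------------------


@dataclass
class CrossConfig:
    """Configuration of a simulated cross.

    ``generation`` 2 means F2 (one meiosis pair from the F1); higher values
    are produced by repeated selfing with independent meioses. Crossovers per
    inter-marker interval are Poisson(d_cM/100) — the Haldane model, no
    interference. ``suppression_intervals`` (cM) receive zero crossovers in
    meioses of individuals heterozygous for the inversion; ``halo_cM`` extends
    each suppression interval on both sides (the suppressed block in real
    crosses can extend beyond the physical inversion)."""

    n_individuals: int
    marker_positions_cM: list[float]
    generation: int = 2
    suppression_intervals: list[tuple[float, float]] = field(default_factory=list)
    dominance_mask: list[bool] | None = None
    seed: int = 0
    halo_cM: float = 0.0
    marker_names: list[str] | None = None
    marker_ref_positions_bp: list[int] | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.generation < 2:
            raise ValueError("generation must be >= 2")
        pos = list(self.marker_positions_cM)
        if len(pos) == 0:
            raise ValueError("marker list must be nonempty")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("marker map positions must be strictly increasing")
        for a, b in self.suppression_intervals:
            if b <= a:
                raise ValueError("suppression interval must have positive length")
            if b < pos[0] or a > pos[-1]:
                raise ValueError("suppression interval outside map range")
        if self.dominance_mask is not None and len(self.dominance_mask) != len(pos):
            raise ValueError("dominance_mask length must match marker count")


@dataclass
class MeiosisRecord:
    """Crossover positions realized in one gamete."""

    generation: int
    individual: int
    gamete: int
    positions: np.ndarray
    parent_inversion_het: bool


def _merge_intervals(ivs: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for a, b in sorted(ivs):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _open_subsegments(a: float, b: float, supp: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Parts of (a, b) not covered by the suppression union."""
    segs = []
    cur = a
    for s, e in supp:
        if e <= cur or s >= b:
            continue
        if s > cur:
            segs.append((cur, min(s, b)))
        cur = max(cur, e)
        if cur >= b:
            break
    if cur < b:
        segs.append((cur, b))
    return segs


def simulate_cross(
    config: CrossConfig,
    parent_labels: tuple[str, str] = ("P1", "P2"),
    inversion_het: bool = False,
) -> tuple[GenotypeTable, list[MeiosisRecord]]:
    """Simulate an F_n progeny and return genotypes plus crossover truth.

    The F1 carries one haplotype from each parent (alleles a and b at every
    marker). When ``inversion_het`` is true the two F1 haplotypes carry
    different chromosomal arrangements, and every meiosis of an
    arrangement-heterozygous individual receives zero crossovers inside the
    suppression intervals. Later generations are produced by selfing;
    arrangement homozygotes recombine freely (their crossovers exchange
    identical-origin segments, so no observable recombinant genotypes arise
    inside the block).
    """
    pos = np.asarray(config.marker_positions_cM, dtype=float)
    m = pos.size
    n = config.n_individuals
    rng = np.random.default_rng(config.seed)

    supp = _merge_intervals(
        [(a - config.halo_cM, b + config.halo_cM) for a, b in config.suppression_intervals]
    )
    d = np.diff(pos)
    open_segs = [_open_subsegments(pos[j], pos[j + 1], supp) for j in range(m - 1)]
    d_open = np.array([sum(e - s for s, e in segs) for segs in open_segs])
    lam_full = d / 100.0
    lam_het = d_open / 100.0

    # marker used to read off which arrangement a gamete inherited: the first
    # marker inside the (crossover-free, hence intact) suppressed block
    inv_idx = 0
    for a, b in supp:
        inside = np.flatnonzero((pos >= a) & (pos <= b))
        if inside.size:
            inv_idx = int(inside[0])
            break

    hap_alleles = np.zeros((n, 2, m), dtype=np.int8)
    hap_alleles[:, 1, :] = 1
    hap_inv = np.zeros((n, 2), dtype=np.int8)
    if inversion_het:
        hap_inv[:, 1] = 1

    rows = np.arange(n)
    log: list[MeiosisRecord] = []

    def meiosis(generation: int, gamete_no: int):
        het = hap_inv[:, 0] != hap_inv[:, 1]
        if m > 1:
            lam = np.where(het[:, None], lam_het[None, :], lam_full[None, :])
            counts = rng.poisson(lam)
            parity = np.cumsum(counts, axis=1) % 2
        else:
            counts = np.zeros((n, 0), dtype=int)
            parity = np.zeros((n, 0), dtype=int)
        start = rng.integers(0, 2, size=n)
        hap_at = np.empty((n, m), dtype=np.int8)
        hap_at[:, 0] = start
        if m > 1:
            hap_at[:, 1:] = (start[:, None] + parity) % 2
        gam = hap_alleles[rows[:, None], hap_at, np.arange(m)[None, :]]
        gam_inv = hap_inv[rows, hap_at[:, inv_idx]]
        for i, j in zip(*np.nonzero(counts)):
            c = int(counts[i, j])
            segs = open_segs[j] if het[i] else [(pos[j], pos[j + 1])]
            lens = np.array([e - s for s, e in segs])
            pick = rng.choice(len(segs), size=c, p=lens / lens.sum())
            u = rng.random(c)
            xp = np.sort(np.array([segs[t][0] + u[q] * (segs[t][1] - segs[t][0]) for q, t in enumerate(pick)]))
            log.append(MeiosisRecord(generation, int(i), gamete_no, xp, bool(het[i])))
        return gam, gam_inv

    for gen in range(2, config.generation + 1):
        g1, i1 = meiosis(gen, 0)
        g2, i2 = meiosis(gen, 1)
        hap_alleles = np.stack([g1, g2], axis=1)
        hap_inv = np.stack([i1, i2], axis=1)

    allele_sum = hap_alleles[:, 0, :] + hap_alleles[:, 1, :]
    code = np.where(allele_sum == 0, "A", np.where(allele_sum == 2, "B", "H")).astype(object)
    if config.dominance_mask is not None:
        dom = np.asarray(config.dominance_mask, dtype=bool)
        ah = dom[None, :] & ((code == "A") | (code == "H"))
        code[ah] = "AH"

    names = config.marker_names or [f"M{j + 1}" for j in range(m)]
    refpos = config.marker_ref_positions_bp or [0] * m
    dom_mask = config.dominance_mask or [False] * m
    markers = [
        Marker(
            name=names[j],
            ref_pos_bp=int(refpos[j]),
            map_pos_cM=float(pos[j]),
            assay="dominant" if dom_mask[j] else "codominant",
        )
        for j in range(m)
    ]
    ids = [f"{parent_labels[0]}x{parent_labels[1]}_F{config.generation}_{i + 1:05d}" for i in range(n)]
    calls = pd.DataFrame(np.asarray(code), index=ids, columns=names)
    return GenotypeTable(markers=markers, calls=calls), log
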