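"""Strand-aware anchoring, chaining, inversion calling and dot-plot export.

Anchors are maximal runs of shared k-mers that are unique (or rare, up to
``max_occurrences`` counting both strands) in both sequences. Uniqueness
automatically masks repeat families such as the inverted resistance-gene
cassettes that flank real inversions, so breakpoint intervals come out
anchor-free. Anchors are chained greedily in target order into same-strand
collinear blocks; a maximal run of minus-strand blocks flanked by plus-strand
blocks (or sequence ends) is an inversion call.

Coordinates are 0-based half-open. For minus-strand anchors, the query
interval read forward matches the reverse complement of the target interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import SequenceRecord, encode, kmer_codes, revcomp

DEFAULT_K = 21
DEFAULT_MAX_OCCURRENCES = 1
DEFAULT_MAX_GAP = 10_000
DEFAULT_MAX_DIAG_DRIFT = 2_000
DEFAULT_MIN_BLOCK_ANCHORS = 1
DEFAULT_MIN_INVERSION_SIZE = 10_000


@dataclass(frozen=True)
class Anchor:
    """An exact shared segment between query and target."""

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.q_end - self.q_start != self.t_end - self.t_start:
            raise ValueError("query and target spans must have equal length")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


@dataclass
class AnchorSet:
    """Anchors between one query and one target sequence."""

    anchors: list[Anchor] = field(default_factory=list)
    query_id: str = ""
    target_id: str = ""

    def __len__(self) -> int:
        return len(self.anchors)

    def __iter__(self):
        return iter(self.anchors)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "q_start": a.q_start,
                    "q_end": a.q_end,
                    "t_start": a.t_start,
                    "t_end": a.t_end,
                    "strand": a.strand,
                }
                for a in self.anchors
            ],
            columns=["q_start", "q_end", "t_start", "t_end", "strand"],
        )


@dataclass
class SyntenyBlock:
    """A chained run of same-strand anchors (a collinear segment)."""

    anchors: list[Anchor]
    strand: str

    @property
    def q_span(self) -> tuple[int, int]:
        return (min(a.q_start for a in self.anchors), max(a.q_end for a in self.anchors))

    @property
    def t_span(self) -> tuple[int, int]:
        return (min(a.t_start for a in self.anchors), max(a.t_end for a in self.anchors))

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def coverage_bp(self) -> int:
        return sum(a.length for a in self.anchors)


@dataclass
class InversionCall:
    """An orientation-flipped segment, reported in target coordinates."""

    t_interval: tuple[int, int]
    q_interval: tuple[int, int]
    left_breakpoint_interval: tuple[int, int]
    right_breakpoint_interval: tuple[int, int]

    @property
    def size_t(self) -> int:
        return self.t_interval[1] - self.t_interval[0]

    @property
    def size_q(self) -> int:
        return self.q_interval[1] - self.q_interval[0]


# ---------------------------------------------------------------------------
# anchor finding
# ---------------------------------------------------------------------------


def _both_strand_counts(codes: np.ndarray, rc_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    allc = np.concatenate([codes, rc_codes])
    return np.unique(allc, return_counts=True)


def _counts_of(uniq: np.ndarray, cnt: np.ndarray, codes: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(uniq, codes)
    idx = np.clip(idx, 0, uniq.size - 1)
    out = cnt[idx]
    out[uniq[idx] != codes] = 0
    return out


def _join(q_codes, q_pos, t_codes, t_pos):
    """All (q, t) position pairs with equal codes."""
    order = np.argsort(t_codes, kind="stable")
    ts, tp = t_codes[order], t_pos[order]
    left = np.searchsorted(ts, q_codes, side="left")
    right = np.searchsorted(ts, q_codes, side="right")
    counts = right - left
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    qi = np.repeat(np.arange(q_codes.size), counts)
    offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    ti = np.repeat(left, counts) + offs
    return q_pos[qi], tp[ti]


def _merge_seeds(qp: np.ndarray, op: np.ndarray, k: int) -> list[tuple[int, int, int, int]]:
    """Merge same-diagonal overlapping/adjacent seeds into maximal runs.

    ``op`` is the seed position on the (possibly reverse-complemented) target.
    Returns (q_start, q_end, o_start, o_end) runs.
    """
    if qp.size == 0:
        return []
    diag = op - qp
    order = np.lexsort((qp, diag))
    qs, ds = qp[order], diag[order]
    new_run = np.empty(qs.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = (np.diff(ds) != 0) | (np.diff(qs) > k)
    starts = np.flatnonzero(new_run)
    ends = np.append(starts[1:], qs.size)
    runs = []
    for s, e in zip(starts, ends):
        q0, q1 = int(qs[s]), int(qs[e - 1]) + k
        d = int(ds[s])
        runs.append((q0, q1, q0 + d, q1 + d))
    return runs


def find_anchors(
    query: SequenceRecord,
    target: SequenceRecord,
    k: int = DEFAULT_K,
    max_occurrences: int = DEFAULT_MAX_OCCURRENCES,
) -> AnchorSet:
    """All maximal shared-k-mer anchors between query and target.

    k-mers occurring more than ``max_occurrences`` times in either sequence
    (counting both strands) are dropped, as are k-mers containing N.
    Overlapping or adjacent same-diagonal seeds are merged into maximal
    anchors. A k larger than either sequence yields an empty set.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    result = AnchorSet(query_id=query.id, target_id=target.id)
    if k > len(query) or k > len(target):
        return result

    t_arr = target.codes
    q_arr = query.codes
    trc_arr = encode(revcomp(target.seq))
    qrc_arr = encode(revcomp(query.seq))

    T, Tv = kmer_codes(t_arr, k)
    Trc, Trcv = kmer_codes(trc_arr, k)
    Q, Qv = kmer_codes(q_arr, k)
    Qrc, Qrcv = kmer_codes(qrc_arr, k)

    t_uniq, t_cnt = _both_strand_counts(T[Tv], Trc[Trcv])
    q_uniq, q_cnt = _both_strand_counts(Q[Qv], Qrc[Qrcv])

    q_pos_all = np.flatnonzero(Qv)
    q_codes = Q[q_pos_all]
    ok = (_counts_of(q_uniq, q_cnt, q_codes) <= max_occurrences) & (
        _counts_of(t_uniq, t_cnt, q_codes) <= max_occurrences
    ) & (_counts_of(t_uniq, t_cnt, q_codes) > 0)
    q_codes, q_pos_all = q_codes[ok], q_pos_all[ok]

    t_pos_f = np.flatnonzero(Tv)
    trc_pos = np.flatnonzero(Trcv)

    Lt = len(target)
    anchors: list[Anchor] = []

    qp, tp = _join(q_codes, q_pos_all, T[t_pos_f], t_pos_f)
    for q0, q1, t0, t1 in _merge_seeds(qp, tp, k):
        anchors.append(Anchor(q0, q1, t0, t1, "+"))

    qp, jp = _join(q_codes, q_pos_all, Trc[trc_pos], trc_pos)
    for q0, q1, j0, j1 in _merge_seeds(qp, jp, k):
        anchors.append(Anchor(q0, q1, Lt - j1, Lt - j0, "-"))

    anchors.sort(key=lambda a: (a.t_start, a.q_start, a.strand))
    result.anchors = anchors
    return result


# ---------------------------------------------------------------------------
# chaining and inversion calling
# ---------------------------------------------------------------------------


def _diag(a: Anchor) -> int:
    # constant along a collinear run: offset for '+', anti-diagonal for '-'
    return a.t_start - a.q_start if a.strand == "+" else a.t_start + a.q_end


def chain_anchors(
    anchors: AnchorSet | list[Anchor],
    max_gap: int = DEFAULT_MAX_GAP,
    max_diag_drift: int = DEFAULT_MAX_DIAG_DRIFT,
    min_block_anchors: int = DEFAULT_MIN_BLOCK_ANCHORS,
) -> list[SyntenyBlock]:
    """Greedy same-strand chaining of anchors in target order.

    An anchor joins an open chain of its strand when the target gap to the
    chain end is at most ``max_gap``, the diagonal drift is at most
    ``max_diag_drift``, and query order stays monotone (increasing for '+',
    decreasing for '-'). Chains with fewer than ``min_block_anchors`` anchors
    are discarded. Blocks are returned sorted by target start.
    """
    items = sorted(anchors, key=lambda a: (a.t_start, a.q_start))
    open_chains: list[dict] = []
    blocks: list[SyntenyBlock] = []

    def close(ch):
        if len(ch["anchors"]) >= min_block_anchors:
            blocks.append(SyntenyBlock(anchors=ch["anchors"], strand=ch["strand"]))

    for a in items:
        still_open = []
        for ch in open_chains:
            if a.t_start - ch["t_end"] > max_gap:
                close(ch)
            else:
                still_open.append(ch)
        open_chains = still_open

        best = None
        best_drift = None
        for ch in open_chains:
            if ch["strand"] != a.strand:
                continue
            last = ch["anchors"][-1]
            if a.strand == "+":
                if a.q_start < last.q_start or a.q_end < last.q_end:  # query must advance
                    continue
            else:
                if a.q_start > last.q_start or a.q_end > last.q_end:  # query must retreat
                    continue
            drift = abs(_diag(a) - _diag(last))
            if drift > max_diag_drift:
                continue
            if best is None or drift < best_drift:
                best, best_drift = ch, drift
        if best is None:
            open_chains.append(
                {"strand": a.strand, "anchors": [a], "t_end": a.t_end}
            )
        else:
            best["anchors"].append(a)
            best["t_end"] = max(best["t_end"], a.t_end)

    for ch in open_chains:
        close(ch)
    blocks.sort(key=lambda b: b.t_span[0])
    return blocks


def call_inversions(
    blocks: list[SyntenyBlock], min_size: int = DEFAULT_MIN_INVERSION_SIZE
) -> list[InversionCall]:
    """Inversion calls from target-sorted synteny blocks.

    Each maximal run of minus-strand blocks flanked by plus-strand blocks (or
    a sequence end) whose target span reaches ``min_size`` becomes one call;
    the breakpoint intervals are the anchor-free target gaps between the
    inverted core and its forward flanks. Nested flips inside a minus run are
    not called separately.
    """
    calls: list[InversionCall] = []
    i = 0
    n = len(blocks)
    while i < n:
        if blocks[i].strand != "-":
            i += 1
            continue
        j = i
        while j + 1 < n and blocks[j + 1].strand == "-":
            j += 1
        run = blocks[i : j + 1]
        t0 = min(b.t_span[0] for b in run)
        t1 = max(b.t_span[1] for b in run)
        q0 = min(b.q_span[0] for b in run)
        q1 = max(b.q_span[1] for b in run)
        if t1 - t0 >= min_size:
            left = (blocks[i - 1].t_span[1], t0) if i > 0 else (t0, t0)
            right = (t1, blocks[j + 1].t_span[0]) if j + 1 < n else (t1, t1)
            left = (min(left), max(left))
            right = (min(right), max(right))
            calls.append(
                InversionCall(
                    t_interval=(t0, t1),
                    q_interval=(q0, q1),
                    left_breakpoint_interval=left,
                    right_breakpoint_interval=right,
                )
            )
        i = j + 1
    return calls


# ---------------------------------------------------------------------------
# marker coordinates
# ---------------------------------------------------------------------------


def marker_distance(
    marker_a: str, marker_b: str, marker_table: pd.DataFrame, genome_tag: str
) -> int:
    """Absolute bp distance between two markers on one genome build.

    ``marker_table`` is a long-format table with columns
    ``name, genome, pos_bp``.
    """
    def lookup(name: str) -> int:
        hit = marker_table[(marker_table["name"] == name) & (marker_table["genome"] == genome_tag)]
        if hit.empty:
            raise KeyError(f"marker {name!r} has no coordinate on genome {genome_tag!r}")
        return int(hit["pos_bp"].iloc[0])

    return abs(lookup(marker_a) - lookup(marker_b))


def liftover_position(
    pos: int, build_from: str, build_to: str, offset_pair: tuple[int, int]
) -> int:
    """Constant-offset liftover between two builds of the same region.

    ``offset_pair`` gives one locus's coordinate in (build_from, build_to);
    interval lengths are preserved.
    """
    pair_from, pair_to = offset_pair
    return pos + (pair_to - pair_from)


# ---------------------------------------------------------------------------
# dot-plot export
# ---------------------------------------------------------------------------

_DOTPLOT_COLUMNS = ["q_start", "q_end", "t_start", "t_end", "strand"]


def export_dotplot(anchors: AnchorSet, path, plot_path=None) -> pd.DataFrame:
    """Write anchors as a dot-plot TSV (and optionally a PNG).

    Plus and minus strand anchors are distinguishable via the ``strand``
    column (the conventional red/blue of comparative dot plots).
    """
    df = anchors.to_frame()
    df.to_csv(path, sep="\t", index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        for strand, color in (("+", "red"), ("-", "blue")):
            sub = df[df["strand"] == strand]
            for _, r in sub.iterrows():
                if strand == "+":
                    ax.plot([r.t_start, r.t_end], [r.q_start, r.q_end], color=color, lw=0.8)
                else:
                    ax.plot([r.t_start, r.t_end], [r.q_end, r.q_start], color=color, lw=0.8)
        ax.set_xlabel("target (bp)")
        ax.set_ylabel("query (bp)")
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return df


def read_dotplot(path) -> AnchorSet:
    """Read a dot-plot TSV back into an AnchorSet (round-trip safe)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _DOTPLOT_COLUMNS:
        raise ValueError(f"expected columns {_DOTPLOT_COLUMNS}, got {list(df.columns)}")
    return AnchorSet(
        anchors=[
            Anchor(int(r.q_start), int(r.q_end), int(r.t_start), int(r.t_end), str(r.strand))
            for r in df.itertuples()
        ]
    )
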