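"""Breakpoint localization from split alignments and in-silico PCR.

A clone-sized query (a BAC or contig) is chained against the reference; every
adjacent pair of chained blocks whose reference loci disagree in strand, or
jump further than a threshold, marks a breakpoint, reported as the anchor-free
query interval between the blocks (never a single base — split alignments
bound a breakpoint, they do not pin it). Diagnostic PCR outcomes are predicted
by exact (optionally mismatch-tolerant, 3'-anchored) primer-site search and a
convergent-orientation product rule with a standard-PCR length ceiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import SequenceRecord, encode, revcomp
from .synteny import (
    DEFAULT_K,
    DEFAULT_MAX_DIAG_DRIFT,
    DEFAULT_MAX_GAP,
    DEFAULT_MAX_OCCURRENCES,
    chain_anchors,
    find_anchors,
)

DEFAULT_JUMP_THRESHOLD = 20_000
DEFAULT_MAX_PRODUCT_LEN = 5_000


@dataclass
class BreakpointCall:
    """A split-alignment breakpoint on the query."""

    q_interval: tuple[int, int]
    left_ref_locus: tuple[tuple[int, int], str]
    right_ref_locus: tuple[tuple[int, int], str]
    collinear_prefix_len: int = 0
    kind: str = "strand_switch"  # or "positional_jump"


@dataclass
class PrimerPair:
    """A PCR primer pair with product-size and mismatch policy."""

    fwd_name: str
    fwd_seq: str
    rev_name: str
    rev_seq: str
    max_product_len: int = DEFAULT_MAX_PRODUCT_LEN
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        for name, seq in ((self.fwd_name, self.fwd_seq), (self.rev_name, self.rev_seq)):
            if not 15 <= len(seq) <= 35:
                raise ValueError(f"primer {name!r} length must be 15-35")
            if not set(seq) <= set("ACGT"):
                raise ValueError(f"primer {name!r} must be over ACGT")

    @property
    def name(self) -> str:
        return f"{self.fwd_name}/{self.rev_name}"


@dataclass
class Amplicon:
    """A predicted PCR outcome on one template."""

    template_id: str
    fwd_site: tuple[int, str]
    rev_site: tuple[int, str]
    product_len: int
    status: str  # product | over_max_len


# ---------------------------------------------------------------------------
# breakpoint localization
# ---------------------------------------------------------------------------


def locate_breakpoints(
    query: SequenceRecord,
    target: SequenceRecord,
    k: int = DEFAULT_K,
    max_occurrences: int = DEFAULT_MAX_OCCURRENCES,
    max_gap: int = DEFAULT_MAX_GAP,
    max_diag_drift: int = DEFAULT_MAX_DIAG_DRIFT,
    min_block_anchors: int = 1,
    jump_threshold: int = DEFAULT_JUMP_THRESHOLD,
    from_position: int = 0,
) -> list[BreakpointCall]:
    """Breakpoints in a query against the reference.

    A breakpoint is emitted between query-adjacent blocks that switch strand
    or whose target loci jump by more than ``jump_threshold`` beyond what the
    query gap accounts for. ``from_position`` is a query coordinate (e.g. a
    primer site) from which the collinear prefix length to each breakpoint is
    measured.
    """
    anchors = find_anchors(query, target, k=k, max_occurrences=max_occurrences)
    if len(anchors) == 0:
        warnings.warn(f"query {query.id!r} has no anchors on {target.id!r}")
        return []
    blocks = chain_anchors(
        anchors, max_gap=max_gap, max_diag_drift=max_diag_drift, min_block_anchors=min_block_anchors
    )
    blocks = sorted(blocks, key=lambda b: b.q_span)
    calls: list[BreakpointCall] = []
    for prev, nxt in zip(blocks, blocks[1:]):
        q_gap = nxt.q_span[0] - prev.q_span[1]
        if prev.strand != nxt.strand:
            kind = "strand_switch"
        else:
            if prev.strand == "+":
                t_step = nxt.t_span[0] - prev.t_span[1]
            else:  # minus blocks walk backwards on the target as query advances
                t_step = prev.t_span[0] - nxt.t_span[1]
            if abs(t_step - q_gap) <= jump_threshold:
                continue
            kind = "positional_jump"
        q0, q1 = prev.q_span[1], max(prev.q_span[1], nxt.q_span[0])
        calls.append(
            BreakpointCall(
                q_interval=(q0, q1),
                left_ref_locus=(prev.t_span, prev.strand),
                right_ref_locus=(nxt.t_span, nxt.strand),
                collinear_prefix_len=min(abs(q0 - from_position), abs(q1 - from_position)),
                kind=kind,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------


def _window_mismatches(template: np.ndarray, primer: np.ndarray) -> np.ndarray:
    """Mismatch count of the primer against every template window."""
    n = template.size - primer.size + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    mism = np.zeros(n, dtype=np.int64)
    for j, b in enumerate(primer):
        mism += template[j : j + n] != b
    return mism


def primer_sites(
    template: SequenceRecord, primer_seq: str, max_mismatches: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Primer binding sites on both strands of a template.

    Returns ``(plus_starts, minus_starts)``: a plus site at p means the primer
    extends rightward from p; a minus site at p means the template segment
    ``[p, p+len)`` equals the primer's reverse complement, i.e. the primer
    extends leftward with its 3' end at p. When mismatches are allowed, the
    three 3'-terminal bases must still match exactly.
    """
    tpl = template.codes
    p = encode(primer_seq)
    p_rc = encode(revcomp(primer_seq))
    n = tpl.size - p.size + 1

    def match(pr: np.ndarray, exact_tail: str) -> np.ndarray:
        mism = _window_mismatches(tpl, pr)
        ok = mism <= max_mismatches
        if max_mismatches > 0 and n > 0:
            if exact_tail == "right":
                tail = np.zeros(n, dtype=np.int64)
                for j in range(pr.size - 3, pr.size):
                    tail += tpl[j : j + n] != pr[j]
            else:
                tail = np.zeros(n, dtype=np.int64)
                for j in range(3):
                    tail += tpl[j : j + n] != pr[j]
            ok &= tail == 0
        return np.flatnonzero(ok)

    return match(p, "right"), match(p_rc, "left")


def insilico_pcr(template: SequenceRecord, pair: PrimerPair) -> list[Amplicon]:
    """Predicted amplicons of a primer pair on one template.

    A product requires a convergent arrangement: one primer bound on the plus
    strand upstream of the other primer bound on the minus strand. Convergent
    arrangements longer than ``max_product_len`` are reported with status
    ``over_max_len`` (obtainable only under long-PCR conditions);
    same-orientation or divergent site pairs yield nothing.
    """
    f_plus, f_minus = primer_sites(template, pair.fwd_seq, pair.max_mismatches)
    r_plus, r_minus = primer_sites(template, pair.rev_seq, pair.max_mismatches)
    lf, lr = len(pair.fwd_seq), len(pair.rev_seq)
    out: list[Amplicon] = []

    def emit(plus_starts, minus_starts, plus_len, minus_len, plus_is_fwd: bool):
        for ps in plus_starts.tolist():
            for ms in minus_starts.tolist():
                end = ms + minus_len
                product = end - ps
                if ms < ps + plus_len:  # divergent or nested
                    continue
                status = "product" if product <= pair.max_product_len else "over_max_len"
                fwd_site = (ps, "+") if plus_is_fwd else (ms, "-")
                rev_site = (ms, "-") if plus_is_fwd else (ps, "+")
                out.append(
                    Amplicon(
                        template_id=template.id,
                        fwd_site=fwd_site,
                        rev_site=rev_site,
                        product_len=product,
                        status=status,
                    )
                )

    emit(f_plus, r_minus, lf, lr, plus_is_fwd=True)
    emit(r_plus, f_minus, lr, lf, plus_is_fwd=False)
    out.sort(key=lambda a: (a.product_len, a.fwd_site, a.rev_site))
    return out


def breakpoint_pcr_panel(
    templates: dict[str, SequenceRecord], pairs: list[PrimerPair]
) -> pd.DataFrame:
    """Presence/absence matrix of predicted PCR outcomes.

    One row per template, one column per pair; cells are the best outcome
    (``product`` > ``over_max_len`` > ``none``).
    """
    rank = {"product": 2, "over_max_len": 1, "none": 0}
    data = {}
    for pname, pair in [(p.name, p) for p in pairs]:
        col = {}
        for tname, tpl in templates.items():
            amps = insilico_pcr(tpl, pair)
            best = max((a.status for a in amps), key=lambda s: rank[s], default="none")
            col[tname] = best
        data[pname] = col
    return pd.DataFrame(data, index=list(templates)).rename_axis("template")


# ---------------------------------------------------------------------------
# diagnostic primer design around a junction
# ---------------------------------------------------------------------------


def _absent_from(window: str, others: list[SequenceRecord]) -> bool:
    rc = revcomp(window)
    return all(window not in o.seq and rc not in o.seq for o in others)


def pick_specific_primer(
    source: SequenceRecord,
    start: int,
    direction: int,
    avoid: list[SequenceRecord],
    primer_len: int = 22,
    scan: int = 2000,
) -> tuple[str, int]:
    """First primer-length window from ``start`` (scanning in ``direction``)
    absent, on both strands, from every template in ``avoid``.

    This is ordinary junction-diagnostic primer design: a primer that is
    template-specific because it covers divergence between the templates.
    Returns the window sequence (template plus strand) and its start.
    """
    for off in range(0, scan):
        s = start + direction * off
        if s < 0 or s + primer_len > len(source):
            break
        window = source.seq[s : s + primer_len]
        if "N" in window:
            continue
        if _absent_from(window, avoid):
            return window, s
    raise ValueError("no template-specific primer window found in the scanned range")


def design_junction_pair(
    template_on: SequenceRecord,
    junction: int,
    avoid_fwd: list[SequenceRecord],
    avoid_rev: list[SequenceRecord],
    primer_len: int = 22,
    offset: int = 150,
    max_product_len: int = DEFAULT_MAX_PRODUCT_LEN,
    name: str = "junction",
) -> PrimerPair:
    """Design a junction-spanning diagnostic pair on ``template_on``.

    The forward primer is picked upstream of the junction and required to be
    absent from ``avoid_fwd`` templates; the reverse primer downstream,
    absent from ``avoid_rev``. A template then yields a product only if it
    carries both sides of the junction.
    """
    fwd, fs = pick_specific_primer(
        template_on, junction - offset - primer_len, -1, avoid_fwd, primer_len
    )
    rev_win, rs = pick_specific_primer(template_on, junction + offset, +1, avoid_rev, primer_len)
    return PrimerPair(
        fwd_name=f"{name}F",
        fwd_seq=fwd,
        rev_name=f"{name}R",
        rev_seq=revcomp(rev_win),
        max_product_len=max_product_len,
    )
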