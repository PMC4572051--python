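"""Readers/writers for the standard formats, configuration, and the pipeline driver.

FASTA goes through Biopython; genotype tables, marker maps and dot plots are
plain TSV. ``run_pipeline`` wires the stages together on a fully synthetic
study system — generate a reference/wild pair with a known inversion, compare
them, rebuild the wild superscaffold from shuffled scaffolds, run the genetic
parsimony and suppression analyses on simulated crosses, localize the
inversion breakpoint in a clone-sized query from the introgression line, and
predict the diagnostic PCR panel — then writes a machine-readable report with
every result next to its ground truth.

All randomness flows from ``master_seed``; per-stage seeds are derived as
``(master_seed * 1000 + stage_offset) mod 2**31`` with fixed documented
offsets (reference 1, wild 2, fragmentation 3, intraspecific cross 4,
interspecific F2 5, interspecific F4 6).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from . import breakpoint as bp
from . import genetics, scaffolding, synteny, synthetic_data
from .genetics import CODE_STATES, GenotypeTable, Marker
from .records import SequenceRecord

logger = logging.getLogger("invscan")

_SEED_OFFSETS = {
    "reference": 1,
    "wild": 2,
    "fragmentation": 3,
    "cross_intra": 4,
    "cross_inter_f2": 5,
    "cross_inter_f4": 6,
}


def stage_seed(master_seed: int, stage: str) -> int:
    return (master_seed * 1000 + _SEED_OFFSETS[stage]) % (2**31)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords.

    Mixed-case input is uppercased with a warning; ``offset=``/``build=``
    tokens in the description (written by :func:`write_fasta`) are restored.
    Sequence data before the first header is a parse error with the line
    number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if not s.startswith(">"):
                raise ValueError(f"{path}:{lineno}: sequence data before first FASTA header")
            break
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"record {rec.id!r}: mixed-case sequence uppercased")
            seq = seq.upper()
        offset = 0
        build = ""
        for token in rec.description.split()[1:]:
            if token.startswith("offset="):
                offset = int(token[7:])
            elif token.startswith("build="):
                build = token[6:]
        records.append(SequenceRecord(id=rec.id, seq=seq, origin_offset=offset, build_tag=build))
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    """Write SequenceRecords as 60-column FASTA, keeping provenance tokens."""
    bio = []
    for r in records:
        desc = f"offset={r.origin_offset}" + (f" build={r.build_tag}" if r.build_tag else "")
        bio.append(BioSeqRecord(Seq(r.seq), id=r.id, description=desc))
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# genotype tables and marker maps
# ---------------------------------------------------------------------------


def write_genotype_table(table: GenotypeTable, path) -> None:
    df = table.calls.copy()
    df.index.name = "individual"
    df.to_csv(path, sep="\t")


def read_genotype_table(path, markers: list[Marker] | None = None) -> GenotypeTable:
    """Read an individuals x markers TSV of codes {A,H,B,AH,-}.

    Ragged rows and unknown codes are rejected with the offending individual
    and marker named. If no marker metadata is supplied, bare markers are
    created from the header.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        names = header[1:]
        rows = []
        ids = []
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(f"{path}: ragged row for individual {fields[0]!r}")
            ids.append(fields[0])
            for name, code in zip(names, fields[1:]):
                if code not in CODE_STATES:
                    raise ValueError(
                        f"{path}: unknown genotype code {code!r} for individual "
                        f"{fields[0]!r} at marker {name!r}"
                    )
            rows.append(fields[1:])
    if markers is None:
        markers = [Marker(name=n) for n in names]
    elif [m.name for m in markers] != names:
        raise ValueError("marker map does not match genotype table header")
    calls = pd.DataFrame(rows, index=ids, columns=names, dtype=object)
    return GenotypeTable(markers=markers, calls=calls)


def write_marker_map(markers: list[Marker], path) -> None:
    pd.DataFrame(
        [
            {
                "name": m.name,
                "ref_pos_bp": m.ref_pos_bp,
                "map_pos_cM": m.map_pos_cM,
                "assay": m.assay,
            }
            for m in markers
        ]
    ).to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> list[Marker]:
    df = pd.read_csv(path, sep="\t")
    return [
        Marker(
            name=str(r["name"]),
            ref_pos_bp=int(r["ref_pos_bp"]),
            map_pos_cM=None if pd.isna(r["map_pos_cM"]) else float(r["map_pos_cM"]),
            assay=str(r["assay"]),
        )
        for _, r in df.iterrows()
    ]


def write_bed(intervals: list[tuple[str, int, int, str]], path) -> None:
    """Write (chrom, start, end, name) rows as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Full parameterization of the synthetic end-to-end run.

    Defaults encode the emulated study system: a 1-Mb AT-rich region, a
    200-kb inversion flanked by 3-kb inverted cassettes, 2% SNP / 0.1% indel
    divergence, a three-scaffold draft fragmentation with 606-bp and 4.3-kb
    gaps, a 300-kb introgression, and intraspecific (collinear) plus
    interspecific (inversion-heterozygous) crosses over six markers.
    """

    master_seed: int = 7
    output_dir: str = "invscan_out"
    verbosity: str = "INFO"

    # simulation
    ref_length: int = 1_000_000
    gc: float = 0.36
    snp_rate: float = 0.02
    indel_rate: float = 0.001
    inversion_start: int = 300_000
    inversion_end: int = 500_000
    cassette_len: int = 3_000
    cassette_identity: float = 0.95
    n_gap_runs: int = 3
    scaffold_breaks: list[int] = field(default_factory=lambda: [150_000, 650_000])
    scaffold_gap_sizes: list[int] = field(default_factory=lambda: [606, 4_300])
    introgression_segment: list[int] = field(default_factory=lambda: [250_000, 550_000])
    marker_ref_positions: list[int] = field(
        default_factory=lambda: [100_000, 250_000, 330_000, 470_000, 550_000, 700_000]
    )
    cM_per_Mbp: float = 25.0
    n_intraspecific: int = 100
    n_interspecific_f2: int = 88
    n_interspecific_f4: int = 11_000

    # synteny / scaffolding / breakpoint
    k: int = 21
    max_occurrences: int = 1
    max_gap: int = 10_000
    max_diag_drift: int = 2_000
    min_block_anchors: int = 3
    min_inversion_size: int = 10_000
    jump_threshold: int = 20_000
    bac_half_width: int = 25_000

    # genetics / pcr
    alpha: float = 0.05
    max_product_len: int = 5_000
    primer_len: int = 22

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


def _wild_marker_positions(truth, ref_positions: list[int]) -> list[int]:
    """Map marker positions through the inversion to wild coordinates."""
    inv = truth.inversion
    out = []
    for p in ref_positions:
        if inv is not None and inv.start <= p < inv.end:
            # inside the inversion the wild copy runs in reverse
            wb0, wb1 = truth.wild_breakpoints
            frac_from_end = (inv.end - p) / (inv.end - inv.start)
            out.append(int(wb0 + frac_from_end * (wb1 - wb0)))
        else:
            out.append(truth.ref_to_wild(p))
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute simulate -> synteny -> scaffold -> parsimony -> breakpoint -> PCR.

    Returns the structured report (also written as ``report.json`` and a
    human-readable ``report.txt``; coordinates in the text report are 1-based
    closed, all JSON coordinates 0-based half-open).
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"master_seed": config.master_seed, "coordinate_system": "0-based half-open"}

    # --- stage 1: simulate -------------------------------------------------
    logger.info("stage simulate: seed=%d length=%d", config.master_seed, config.ref_length)
    ref = synthetic_data.generate_reference(
        config.ref_length, gc=config.gc, seed=stage_seed(config.master_seed, "reference")
    )
    inv = synthetic_data.InversionSpec(
        config.inversion_start,
        config.inversion_end,
        cassette_len=config.cassette_len,
        cassette_identity=config.cassette_identity,
    )
    wild, truth = synthetic_data.derive_wild_genome(
        ref,
        snp_rate=config.snp_rate,
        indel_rate=config.indel_rate,
        inversion=inv,
        n_gap_runs=config.n_gap_runs,
        seed=stage_seed(config.master_seed, "wild"),
    )
    scaffolds, scf_truth = synthetic_data.fragment_scaffolds(
        wild,
        config.scaffold_breaks,
        config.scaffold_gap_sizes,
        shuffle_seed=stage_seed(config.master_seed, "fragmentation"),
        truth=truth,
    )
    seg = tuple(config.introgression_segment)
    introgression, junctions = synthetic_data.make_introgression_line(ref, wild, seg, truth)
    write_fasta([ref], outdir / "reference.fasta")
    write_fasta([wild], outdir / "wild.fasta")
    write_fasta(scaffolds, outdir / "scaffolds.fasta")
    write_fasta([introgression], outdir / "introgression.fasta")
    truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)

    # --- stage 2: synteny --------------------------------------------------
    logger.info("stage synteny: k=%d", config.k)
    anchors = synteny.find_anchors(wild, ref, k=config.k, max_occurrences=config.max_occurrences)
    synteny.export_dotplot(anchors, outdir / "dotplot.tsv")
    blocks = synteny.chain_anchors(
        anchors,
        max_gap=config.max_gap,
        max_diag_drift=config.max_diag_drift,
        min_block_anchors=config.min_block_anchors,
    )
    calls = synteny.call_inversions(blocks, min_size=config.min_inversion_size)
    write_bed(
        [(ref.id, b.t_span[0], b.t_span[1], f"block_{b.strand}_{b.coverage_bp}bp") for b in blocks],
        outdir / "blocks.bed",
    )
    write_bed(
        [(ref.id, c.t_interval[0], c.t_interval[1], f"inversion_{c.size_t}bp") for c in calls],
        outdir / "inversions.bed",
    )
    inv_report = {
        "n_calls": len(calls),
        "truth_t_interval": list(truth.ref_breakpoints) if truth.ref_breakpoints else None,
        "calls": [
            {
                "t_interval": list(c.t_interval),
                "q_interval": list(c.q_interval),
                "size_t": c.size_t,
                "left_breakpoint_interval": list(c.left_breakpoint_interval),
                "right_breakpoint_interval": list(c.right_breakpoint_interval),
            }
            for c in calls
        ],
    }
    if calls and truth.ref_breakpoints:
        best = max(calls, key=lambda c: c.size_t)
        inv_report["boundary_error_bp"] = [
            abs(best.t_interval[0] - truth.ref_breakpoints[0]),
            abs(best.t_interval[1] - truth.ref_breakpoints[1]),
        ]
        tol = config.cassette_len + config.k
        inv_report["recovered_within_cassette_plus_k"] = bool(
            max(inv_report["boundary_error_bp"]) <= tol
        )
    report["inversion"] = inv_report

    # --- stage 3: scaffolding ---------------------------------------------
    logger.info("stage scaffolding: %d scaffolds", len(scaffolds))
    placements, unplaced = scaffolding.place_scaffolds(
        scaffolds,
        ref,
        k=config.k,
        max_occurrences=config.max_occurrences,
        max_gap=config.max_gap,
        max_diag_drift=config.max_diag_drift,
        min_block_anchors=config.min_block_anchors,
    )
    placements = scaffolding.estimate_gaps(placements)
    superscaffold = scaffolding.build_superscaffold(placements, scaffolds)
    scaffolding.placements_to_frame(placements).to_csv(outdir / "placements.tsv", sep="\t", index=False)
    scaffolding.write_agp(superscaffold, outdir / "superscaffold.agp")
    write_fasta([superscaffold.record], outdir / "superscaffold.fasta")

    # truth comparison: true emitted orientation vs reference, in true order
    true_order = [row["id"] for row in scf_truth]
    # a scaffold emitted flipped ('-' in truth) should be placed '-' on the reference
    true_orient = {row["id"]: row["orientation"] for row in scf_truth}
    placed_order = [p.scaffold_id for p in placements]
    orient_ok = all(p.orientation == true_orient[p.scaffold_id] for p in placements)
    gap_rows = []
    for (left, right, true_gap), p in zip(truth.scaffold_gaps, placements[:-1]):
        est = p.est_gap_to_next
        gap_rows.append({"left": left, "right": right, "true_gap": true_gap, "estimated_gap": est})
    report["scaffolding"] = {
        "placed_order": placed_order,
        "true_order": true_order,
        "order_recovered": placed_order == true_order,
        "orientation_recovered": orient_ok,
        "unplaced": unplaced,
        "gaps": gap_rows,
        "superscaffold_length": len(superscaffold.record),
    }

    # --- stage 4: genetics --------------------------------------------------
    logger.info("stage genetics")
    names = [f"M{i + 1}" for i in range(len(config.marker_ref_positions))]
    wild_pos = _wild_marker_positions(truth, config.marker_ref_positions)
    true_perm = [int(i) for i in np.argsort(wild_pos)]  # true (wild) order as ref-order indices
    rate = config.cM_per_Mbp / 1e6
    wild_sorted = sorted(wild_pos)
    cm_positions = [p * rate for p in wild_sorted]
    names_true_order = [names[i] for i in true_perm]

    intra_cfg = synthetic_data.CrossConfig(
        n_individuals=config.n_intraspecific,
        marker_positions_cM=cm_positions,
        marker_names=names_true_order,
        marker_ref_positions_bp=[config.marker_ref_positions[i] for i in true_perm],
        seed=stage_seed(config.master_seed, "cross_intra"),
    )
    intra_table, _ = synthetic_data.simulate_cross(intra_cfg, parent_labels=("Hab1", "Hab2"))
    # present the table in reference order, as a screening lab would
    ref_markers = [intra_table.markers[names_true_order.index(n)] for n in names]
    intra_ref = GenotypeTable(markers=ref_markers, calls=intra_table.calls[names])
    write_genotype_table(intra_ref, outdir / "genotypes_intraspecific.tsv")
    write_marker_map(ref_markers, outdir / "markers.tsv")

    ranked = genetics.best_order(intra_ref)
    winner = ranked[0]
    ref_total = next(
        r.total_crossovers for r in ranked if r.order.permutation == tuple(range(len(names)))
    )
    truth_label_perm = tuple(true_perm)
    report["parsimony"] = {
        "winner_order": list(winner.order.permutation),
        "winner_label": winner.order.label,
        "winner_total_crossovers": winner.total_crossovers,
        "reference_total_crossovers": ref_total,
        "margin_vs_reference": ref_total - winner.total_crossovers,
        "true_order": list(truth_label_perm),
        "true_order_recovered": winner.order.permutation == truth_label_perm
        or winner.order.permutation == tuple(reversed(truth_label_perm)),
    }

    # interspecific crosses: suppression inside the heterozygous inversion
    if truth.wild_breakpoints is not None:
        supp_list = [(truth.wild_breakpoints[0] * rate, truth.wild_breakpoints[1] * rate)]
        inner = [
            n
            for n, p in zip(names_true_order, wild_sorted)
            if supp_list[0][0] <= p * rate <= supp_list[0][1]
        ]
    else:  # collinear genomes: nothing suppressed; report the middle pair
        supp_list = []
        mid = len(names_true_order) // 2
        inner = names_true_order[mid - 1 : mid + 1]
    inter_kwargs = dict(
        marker_positions_cM=cm_positions,
        marker_names=names_true_order,
        marker_ref_positions_bp=[config.marker_ref_positions[i] for i in true_perm],
        suppression_intervals=supp_list,
    )
    f2_cfg = synthetic_data.CrossConfig(
        n_individuals=config.n_interspecific_f2,
        seed=stage_seed(config.master_seed, "cross_inter_f2"),
        **inter_kwargs,
    )
    f2_table, _ = synthetic_data.simulate_cross(f2_cfg, ("Lyc", "Hab"), inversion_het=True)
    f4_cfg = synthetic_data.CrossConfig(
        n_individuals=config.n_interspecific_f4,
        generation=4,
        seed=stage_seed(config.master_seed, "cross_inter_f4"),
        **inter_kwargs,
    )
    f4_table, _ = synthetic_data.simulate_cross(f4_cfg, ("Lyc", "Hab"), inversion_het=True)
    write_genotype_table(f2_table, outdir / "genotypes_interspecific_f2.tsv")

    pair = (inner[0], inner[-1])
    physical = abs(
        config.marker_ref_positions[names.index(pair[0])]
        - config.marker_ref_positions[names.index(pair[1])]
    )
    supp_f2 = genetics.detect_suppression(
        f2_table, [pair], [physical], config.cM_per_Mbp, alpha=config.alpha
    )
    rf_f4 = genetics.recombination_fraction(f4_table, pair[0], pair[1])
    rf_intra = genetics.recombination_fraction(intra_ref, pair[0], pair[1])
    report["suppression"] = {
        "pair": list(pair),
        "physical_bp": physical,
        "f2_n": config.n_interspecific_f2,
        "f2_recombinants": int(supp_f2["n_recombinant"].iloc[0]),
        "f2_flagged_suppressed": bool(supp_f2["suppressed"].iloc[0]),
        "f4_n": config.n_interspecific_f4,
        "f4_recombinants": rf_f4["n_recombinant_individuals"],
        "intraspecific_recombinants_same_pair": rf_intra["n_recombinant_individuals"],
        "intraspecific_cM_same_pair": rf_intra["cM_haldane"],
    }

    # --- stage 5: breakpoint -----------------------------------------------
    logger.info("stage breakpoint")
    # clone-sized query from the introgression line spanning the left
    # inversion breakpoint (the arrangement junction the introgression carries);
    # without an inversion, span the recombinant junction itself (collinear)
    wseg_start = truth.ref_to_wild(seg[0])
    if truth.wild_breakpoints is not None:
        bp_in_intro = seg[0] + (truth.wild_breakpoints[0] - wseg_start)
    else:
        bp_in_intro = seg[0]
    half = config.bac_half_width
    bac = SequenceRecord(
        id="bac_breakpoint",
        seq=introgression.seq[bp_in_intro - half : bp_in_intro + half],
        origin_offset=bp_in_intro - half,
        build_tag="introgression",
    )
    write_fasta([bac], outdir / "bac.fasta")
    bp_calls = bp.locate_breakpoints(
        bac,
        ref,
        k=config.k,
        max_occurrences=config.max_occurrences,
        max_gap=config.max_gap,
        max_diag_drift=config.max_diag_drift,
        min_block_anchors=config.min_block_anchors,
        jump_threshold=config.jump_threshold,
    )
    write_bed(
        [(bac.id, c.q_interval[0], c.q_interval[1], c.kind) for c in bp_calls],
        outdir / "breakpoints.bed",
    )
    report["breakpoint"] = {
        "bac_origin_offset": bac.origin_offset,
        "true_junction_on_query": half,
        "n_calls": len(bp_calls),
        "calls": [
            {
                "q_interval": list(c.q_interval),
                "kind": c.kind,
                "left_ref_locus": [list(c.left_ref_locus[0]), c.left_ref_locus[1]],
                "right_ref_locus": [list(c.right_ref_locus[0]), c.right_ref_locus[1]],
            }
            for c in bp_calls
        ],
    }
    if bp_calls:
        nearest = min(bp_calls, key=lambda c: abs((c.q_interval[0] + c.q_interval[1]) / 2 - half))
        err = max(0, nearest.q_interval[0] - half, half - nearest.q_interval[1])
        report["breakpoint"]["junction_error_bp"] = int(err)

    # --- stage 6: in-silico PCR ---------------------------------------------
    logger.info("stage pcr")
    junction_pair = bp.design_junction_pair(
        introgression,
        junctions[0],
        avoid_fwd=[wild],
        avoid_rev=[ref],
        primer_len=config.primer_len,
        max_product_len=config.max_product_len,
        name="bpJct",
    )
    reference_pair = bp.design_junction_pair(
        ref,
        seg[0],
        avoid_fwd=[],
        avoid_rev=[wild],
        primer_len=config.primer_len,
        max_product_len=config.max_product_len,
        name="refSide",
    )
    templates = {"reference": ref, "wild": wild, "introgression": introgression}
    panel = bp.breakpoint_pcr_panel(templates, [junction_pair, reference_pair])
    panel.to_csv(outdir / "pcr_panel.tsv", sep="\t")
    jp, rp = junction_pair.name, reference_pair.name
    pattern_ok = (
        panel.loc["introgression", jp] == "product"
        and panel.loc["reference", jp] in ("none", "over_max_len")
        and panel.loc["wild", jp] == "none"
        and panel.loc["reference", rp] == "product"
        and panel.loc["introgression", rp] == "none"
    )
    report["pcr"] = {
        "panel": {t: dict(panel.loc[t]) for t in panel.index},
        "junction_pair": jp,
        "reference_pair": rp,
        "diagnostic_pattern_reproduced": bool(pattern_ok),
    }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_text_report(report, outdir / "report.txt")
    return report


def _fmt_1based(interval) -> str:
    return f"{interval[0] + 1}..{interval[1]}"


def _write_text_report(report: dict, path) -> None:
    lines = [
        "invscan pipeline report (coordinates 1-based closed)",
        f"master seed: {report['master_seed']}",
        "",
        "[inversion]",
    ]
    inv = report["inversion"]
    truth_s = _fmt_1based(inv["truth_t_interval"]) if inv["truth_t_interval"] else "none"
    lines.append(f"  calls: {inv['n_calls']}; truth {truth_s}")
    for c in inv["calls"]:
        lines.append(
            f"  call {_fmt_1based(c['t_interval'])} size {c['size_t']} bp; "
            f"breakpoint intervals {_fmt_1based(c['left_breakpoint_interval'])} / "
            f"{_fmt_1based(c['right_breakpoint_interval'])}"
        )
    sc = report["scaffolding"]
    lines += [
        "",
        "[scaffolding]",
        f"  order {' -> '.join(sc['placed_order'])} (recovered: {sc['order_recovered']}; "
        f"orientation recovered: {sc['orientation_recovered']})",
    ]
    for g in sc["gaps"]:
        lines.append(
            f"  gap {g['left']}|{g['right']}: estimated {g['estimated_gap']} bp (true {g['true_gap']})"
        )
    pr = report["parsimony"]
    lines += [
        "",
        "[parsimony]",
        f"  reference order: {pr['reference_total_crossovers']} crossovers; "
        f"winner {pr['winner_label']}: {pr['winner_total_crossovers']} "
        f"(margin {pr['margin_vs_reference']}; true order recovered: {pr['true_order_recovered']})",
    ]
    sup = report["suppression"]
    lines += [
        "",
        "[suppression]",
        f"  pair {sup['pair'][0]}-{sup['pair'][1]} ({sup['physical_bp']} bp): "
        f"F2 n={sup['f2_n']}: {sup['f2_recombinants']} recombinants "
        f"(flagged: {sup['f2_flagged_suppressed']}); "
        f"F4 n={sup['f4_n']}: {sup['f4_recombinants']} recombinants",
        f"  same pair, intraspecific cross: {sup['intraspecific_recombinants_same_pair']} "
        f"recombinants ({sup['intraspecific_cM_same_pair']:.2f} cM)",
    ]
    bpr = report["breakpoint"]
    lines += ["", "[breakpoint]", f"  calls: {bpr['n_calls']}"]
    if "junction_error_bp" in bpr:
        lines.append(f"  junction localization error: {bpr['junction_error_bp']} bp")
    lines += ["", "[pcr]"]
    for tname, row in report["pcr"]["panel"].items():
        lines.append(f"  {tname}: " + ", ".join(f"{k}={v}" for k, v in row.items()))
    lines.append(
        f"  diagnostic pattern reproduced: {report['pcr']['diagnostic_pattern_reproduced']}"
    )
    Path(path).write_text("\n".join(lines) + "\n")
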