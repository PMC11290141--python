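"""End-to-end orchestration: simulate -> call ACRs -> differential ACRs ->
DEGs -> chromatin states -> CRE classification -> triad balance ->
element characterization -> regulatory network.

``run_pipeline`` drives the whole analysis on a synthetic hexaploid
experiment and returns both the stage outputs and evaluation metrics
against the planted ground truth.  All randomness flows from one root
seed via named substreams.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import acr as acrmod
from . import characterize as charmod
from . import chromstate as csmod
from . import cre as cremod
from . import differential as diffmod
from . import network as netmod
from . import synthetic as synmod
from . import triads as trimod
from .genomio import Track, write_bed
from .intervals import Interval, IntervalIndex, merge_intervals
from .motifs import scan_motifs

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "verncre_run"
    seed: int = 0
    synthetic: dict = dc_field(default_factory=dict)
    acr_fdr: float = 0.05
    density_min_fold: float = 2.0
    diff_fdr: float = 0.05
    min_lfc: float = 1.0
    deg_p: float = 0.01
    deg_fold: float = 2.0
    hmm_states: int = 9
    hmm_restarts: int = 2
    hmm_max_iter: int = 100
    bin_size: int = 200
    promoter_dist: int = 2000
    flank: int = 500
    n_shuffles: int = 1000
    motif_p: float = 1e-4
    log_level: str = "INFO"

    _KNOWN = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ------------------------------------------------------------- evaluation

def jaccard_match(
    called: list[Interval], truth: list[Interval], threshold: float = 0.5
) -> tuple[float, float]:
    """(recall, precision) with Jaccard >= threshold interval matching."""
    if not truth or not called:
        return 0.0, 0.0
    called_idx = IntervalIndex(called)
    truth_idx = IntervalIndex(truth)
    hit_t = sum(
        1 for t in truth
        if any(t.jaccard(c) >= threshold for c in called_idx.overlapping(t))
    )
    hit_c = sum(
        1 for c in called
        if any(c.jaccard(t) >= threshold for t in truth_idx.overlapping(c))
    )
    return hit_t / len(truth), hit_c / len(called)


# --------------------------------------------------------------- pipeline

def run_pipeline(config: RunConfig, write_files: bool = True) -> dict:
    """Run every stage on a synthetic experiment; returns results + metrics."""
    t0 = time.time()
    outdir = Path(config.outdir)
    if write_files:
        outdir.mkdir(parents=True, exist_ok=True)
    res: dict = {"config": config}

    # ---- stage 1: synthetic data
    scfg = synmod.SyntheticConfig(**{**config.synthetic, "seed": config.seed})
    genome = synmod.generate_genome(scfg)
    truth = genome.truth
    aux = synmod.plant_auxiliary_features(genome, truth, scfg)
    res["genome"] = genome
    log.info("synthetic genome: %d genes, %d planted ACRs",
             len(genome.genes), len(truth.acrs))

    # ---- stage 2: TIS tracks and per-sample ACR calls
    tis_tracks: dict[str, Track] = {}
    conditions: dict[str, str] = {}
    tis_objects: dict[str, acrmod.TISTrack] = {}
    for cond in synmod.CONDITIONS:
        for rep in range(1, scfg.replicates + 1):
            sid = f"{cond}_{rep}"
            track, lib = synmod.simulate_tis_track(genome, truth, cond, rep, scfg)
            tis_tracks[sid] = track
            conditions[sid] = cond
            tis_objects[sid] = acrmod.TISTrack(track, lib)

    acrs_by_sample = {
        sid: acrmod.call_acrs(t, fdr=config.acr_fdr,
                              density_min_fold=config.density_min_fold)
        for sid, t in tis_objects.items()
    }
    acr_union = merge_intervals(
        [iv for ivs in acrs_by_sample.values() for iv in ivs], 0
    )
    res["acrs_by_sample"] = acrs_by_sample
    res["acr_union"] = acr_union

    planted = truth.acr_intervals()
    recall, precision = jaccard_match(acr_union, planted)
    res["acr_recall"], res["acr_precision"] = recall, precision
    log.info("ACR union: %d regions; planted recall %.3f precision %.3f",
             len(acr_union), recall, precision)

    # ---- stage 3: differential ACRs
    diff_ivs, diff_table = diffmod.diff_acrs(
        acr_union, tis_tracks, conditions,
        bin_size=config.bin_size, fdr=config.diff_fdr, min_lfc=config.min_lfc,
    )
    res["diff_acrs"] = diff_ivs
    res["diff_table"] = diff_table
    truth_resp = truth.responsive_acrs()
    truth_resp_ivs = [
        Interval(r.chrom, int(r.start), int(r.end), name=r.response)
        for r in truth_resp.itertuples()
    ]
    d_recall, d_precision = jaccard_match(diff_ivs, truth_resp_ivs)
    # direction correctness among matched pairs
    diff_idx = IntervalIndex(diff_ivs)
    n_match = n_dir = 0
    for t in truth_resp_ivs:
        for c in diff_idx.overlapping(t):
            if t.jaccard(c) >= 0.5:
                n_match += 1
                n_dir += int(c.name == t.name)
                break
    res["dacr_recall"], res["dacr_precision"] = d_recall, d_precision
    res["dacr_direction_accuracy"] = n_dir / n_match if n_match else float("nan")
    log.info("differential ACRs: %d; responsive recall %.3f precision %.3f",
             len(diff_ivs), d_recall, d_precision)

    # ---- stage 4: expression, TPM, DEGs
    counts = synmod.simulate_expression(genome, truth, scfg)
    lengths = pd.Series(synmod.GENE_LEN, index=counts.index, dtype=float)
    tpm = diffmod.compute_tpm(counts, lengths)
    cond_list = [c.rsplit("_", 1)[0] for c in counts.columns]
    degs = diffmod.call_degs(counts, cond_list, p_max=config.deg_p,
                             min_fold=config.deg_fold,
                             levels=("before", "after"))
    res["expression_counts"], res["tpm"], res["degs"] = counts, tpm, degs

    truth_resp_genes = set(truth.genes[truth.genes.responsive].gene_id)
    called_deg = set(degs[degs.deg != "ns"].index)
    res["deg_sensitivity"] = (
        len(called_deg & truth_resp_genes) / len(truth_resp_genes)
        if truth_resp_genes else float("nan")
    )

    # ---- stage 5: chromatin states
    mark_peaks: dict[str, dict[str, list[Interval]]] = {}
    for cond in synmod.CONDITIONS:
        marks = synmod.simulate_mark_tracks(genome, truth, cond, scfg)
        mark_peaks[cond] = {m: peaks for m, (tr, peaks) in marks.items()}

    chrom_sizes = truth.chrom_sizes
    binarized = {}
    for cond in synmod.CONDITIONS:
        per_track = {"ATAC": csmod.binarize_peaks(
            [iv for sid, ivs in acrs_by_sample.items()
             if conditions[sid] == cond for iv in ivs],
            chrom_sizes, config.bin_size)}
        for m in synmod.MARKS:
            per_track[m] = csmod.binarize_peaks(
                mark_peaks[cond][m], chrom_sizes, config.bin_size)
        binarized[cond] = csmod.stack_tracks(per_track, bin_size=config.bin_size)

    model = csmod.train_hmm(
        binarized["before"], n_states=config.hmm_states,
        max_iter=config.hmm_max_iter, restarts=config.hmm_restarts,
        seed=config.seed,
    )
    label_map = csmod.label_states(model)
    res["hmm_model"], res["hmm_labels"] = model, label_map
    genes = genome.genes
    gene_labels = {}
    for cond in synmod.CONDITIONS:
        _, per_bin = csmod.decode_states(model, binarized[cond], label_map)
        gene_labels[cond] = csmod.gene_state(
            per_bin, label_map, genes, config.bin_size, config.promoter_dist)
    trans, maintained = csmod.state_transitions(
        gene_labels["before"], gene_labels["after"])
    res["state_transitions"], res["maintained_fraction"] = trans, maintained
    truth_maintained = float(
        (truth.genes.state_before == truth.genes.state_after).mean())
    res["truth_maintained_fraction"] = truth_maintained
    # per-gene agreement with the planted states, before condition
    agree = np.mean([
        gene_labels["before"].get(g.gene_id) == s
        for g, s in zip(genes, truth.genes.state_before)
    ])
    res["gene_state_accuracy"] = float(agree)
    log.info("chromatin states: maintained %.3f (truth %.3f), accuracy %.3f",
             maintained, truth_maintained, agree)

    # ---- stage 6: CRE classification of differential ACRs
    seqs = {c: genome.sequence_str(c) for c in chrom_sizes}
    marks_before = cremod.MarkRegions(
        k4me3=mark_peaks["before"]["H3K4me3"],
        k27ac=mark_peaks["before"]["H3K27ac"],
        k27me3=mark_peaks["before"]["H3K27me3"],
        k36me3=mark_peaks["before"]["H3K36me3"],
    )
    triad_of_gene = {
        g: t for t, row in truth.triads.set_index("triad_id").iterrows()
        for g in (row.gene_A, row.gene_B, row.gene_D)
    }
    responses = {f"dACR{i:05d}": iv.name for i, iv in enumerate(diff_ivs)}
    diff_named = [
        Interval(iv.chrom, iv.start, iv.end, name=f"dACR{i:05d}")
        for i, iv in enumerate(diff_ivs)
    ]
    annotation = cremod.annotate_acrs(
        diff_named, genes, marks_before, responses=responses,
        sequences=seqs, triad_of_gene=triad_of_gene,
        promoter_dist=config.promoter_dist, flank=config.flank,
    )
    res["cre_annotation"] = annotation

    # agreement of classes with truth on matched responsive elements
    truth_by_pos = {
        (r.chrom, r.start, r.end): r for r in truth.acrs.itertuples()
    }
    truth_idx2 = IntervalIndex([
        Interval(r.chrom, int(r.start), int(r.end), name=r.acr_id)
        for r in truth.acrs.itertuples()
    ])
    n_cls = n_cls_ok = 0
    truth_acr_by_id = truth.acrs.set_index("acr_id")
    for row in annotation.itertuples():
        iv = Interval(row.chrom, row.start, row.end)
        for hit in truth_idx2.overlapping(iv):
            if iv.jaccard(hit) >= 0.5:
                tr = truth_acr_by_id.loc[hit.name]
                n_cls += 1
                n_cls_ok += int(tr.cre_class == row.cre_class)
                break
    res["cre_class_agreement"] = n_cls_ok / n_cls if n_cls else float("nan")
    # recovery of planted responsive CREs with correct class label
    resp_truth_ids = set(truth_resp.acr_id)
    recovered = 0
    for r in truth_resp.itertuples():
        iv = Interval(r.chrom, int(r.start), int(r.end))
        for row in annotation.itertuples():
            civ = Interval(row.chrom, row.start, row.end)
            if iv.jaccard(civ) >= 0.5 and row.cre_class == r.cre_class:
                recovered += 1
                break
    res["responsive_cre_recovery"] = (
        recovered / len(resp_truth_ids) if resp_truth_ids else float("nan")
    )
    # false discovery among annotated responsive elements
    fp = 0
    for row in annotation.itertuples():
        civ = Interval(row.chrom, row.start, row.end)
        if not any(civ.jaccard(h) >= 0.5 for h in truth_idx2.overlapping(civ)
                   if truth_acr_by_id.loc[h.name].response != "stable"):
            fp += 1
    res["responsive_cre_fdr"] = fp / len(annotation) if len(annotation) else 0.0

    # ---- stage 7: triad balance
    triad_tbl = truth.triads
    tpm_cond = {}
    for cond in synmod.CONDITIONS:
        cols = [c for c in tpm.columns if c.startswith(cond)]
        mean_tpm = tpm[cols].mean(axis=1)
        tpm_cond[cond] = pd.DataFrame({
            "A": mean_tpm.loc[triad_tbl.gene_A].to_numpy(),
            "B": mean_tpm.loc[triad_tbl.gene_B].to_numpy(),
            "D": mean_tpm.loc[triad_tbl.gene_D].to_numpy(),
        }, index=triad_tbl.triad_id)
    cats = {c: trimod.classify_triads(tpm_cond[c]) for c in synmod.CONDITIONS}
    res["triad_categories"] = cats
    res["triad_transitions"] = trimod.balance_transitions(
        cats["before"], cats["after"])
    expr_resp = trimod.classify_triad_responses(
        tpm_cond["before"], tpm_cond["after"])
    res["triad_response"] = expr_resp
    truth_cats = triad_tbl.set_index("triad_id").category
    res["triad_category_accuracy"] = float(
        (cats["before"] == truth_cats.reindex(cats["before"].index)).mean())
    truth_resp_cat = triad_tbl.set_index("triad_id").response_cat
    res["triad_response_accuracy"] = float(
        (expr_resp == truth_resp_cat.reindex(expr_resp.index)).mean())

    # accessibility layer: promoter accessibility per condition
    acc_resp = {}
    acc_cond = {}
    for cond in synmod.CONDITIONS:
        pooled = {
            c: sum(tis_tracks[s][c] for s in tis_tracks if conditions[s] == cond)
            for c in chrom_sizes
        }
        lib = sum(a.sum() for a in pooled.values())
        acc = diffmod.promoter_accessibility(pooled, lib, genes)
        acc_cond[cond] = pd.DataFrame({
            sg: acc.loc[triad_tbl[f"gene_{sg}"]].to_numpy()
            for sg in ("A", "B", "D")
        }, index=triad_tbl.triad_id)
    acc_resp = trimod.classify_triad_responses(
        acc_cond["before"], acc_cond["after"], pseudo=0.1)
    res["triad_association"] = trimod.unbalanced_association(
        expr_resp, {"accessibility": acc_resp})

    # ---- stage 8: element characterization
    rng = np.random.default_rng([config.seed, 7])
    nk4 = annotation[annotation.cre_class == "nK4-dACR"]
    nk4_ivs = [Interval(r.chrom, r.start, r.end, name=r.acr_id)
               for r in nk4.itertuples()]
    gene_idx = IntervalIndex([g.interval.expanded(2000) for g in genes])
    if nk4_ivs:
        nk4_seqs = [seqs[iv.chrom][iv.start:iv.end] for iv in nk4_ivs]
        bg_ivs = charmod.sample_background_intervals(
            nk4_ivs, chrom_sizes, rng, exclude=gene_idx)
        bg_seqs = [seqs[iv.chrom][iv.start:iv.end] for iv in bg_ivs]
        res["gc_comparison"] = charmod.gc_group_comparison(nk4_seqs, bg_seqs)
        res["snp_profile"] = charmod.snp_density_profile(nk4_ivs, truth.snps)
        res["snp_body_flank_ratio"] = charmod.body_flank_ratio(res["snp_profile"])
        all_elem_ivs = [Interval(r.chrom, r.start, r.end, name=r.acr_id)
                        for r in annotation.itertuples()]
        res["gwas_enrichment"] = charmod.overlap_enrichment(
            all_elem_ivs, truth.gwas, chrom_sizes,
            n_shuffles=config.n_shuffles, seed=config.seed)
    specific = [Interval(r.chrom, r.start, r.end) for r in nk4.itertuples()
                if r.homology == "specific"]
    syntenic = [Interval(r.chrom, r.start, r.end) for r in nk4.itertuples()
                if str(r.homology).startswith("syntenic")]
    if specific and syntenic:
        res["te_overlap_specific"] = charmod.te_overlap(
            specific, truth.tes, {"syntenic": syntenic})

    # motif enrichment: responsive vs stable planted distal elements
    resp_distal = truth.acrs[(truth.acrs.cre_class != "promoter")
                             & (truth.acrs.response != "stable")]
    stab_distal = truth.acrs[(truth.acrs.cre_class != "promoter")
                             & (truth.acrs.response == "stable")]
    t_seqs = {r.acr_id: seqs[r.chrom][r.start:r.end]
              for r in resp_distal.itertuples()}
    b_seqs = {r.acr_id: seqs[r.chrom][r.start:r.end]
              for r in stab_distal.itertuples()}
    if t_seqs and b_seqs:
        res["motif_enrichment"] = charmod.motif_enrichment(
            t_seqs, b_seqs, truth.pwms, p_threshold=config.motif_p)

    # ---- stage 9: network
    elem_seqs = {r.acr_id: seqs[r.chrom][r.start:r.end]
                 for r in annotation.itertuples()}
    hits = scan_motifs(elem_seqs, truth.pwms, p_threshold=config.motif_p)
    responsive_genes = called_deg
    edges = netmod.build_network(
        responsive_genes, truth.tf_table, hits, annotation)
    res["network_edges"] = edges
    res["network_summary"] = netmod.network_summary(edges)

    res["runtime_s"] = time.time() - t0
    if write_files:
        _write_outputs(outdir, res, annotation, trans, degs, edges)
    log.info("pipeline finished in %.1f s", res["runtime_s"])
    return res


def _write_outputs(outdir: Path, res: dict, annotation, trans, degs, edges):
    write_bed(outdir / "acr_union.bed", res["acr_union"])
    write_bed(outdir / "diff_acrs.bed", [
        Interval(iv.chrom, iv.start, iv.end, name=iv.name)
        for iv in res["diff_acrs"]
    ])
    annotation.to_csv(outdir / "cre_annotation.tsv", sep="\t", index=False)
    trans.to_csv(outdir / "state_transitions.tsv", sep="\t")
    degs.to_csv(outdir / "degs.tsv", sep="\t")
    edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    res["hmm_model"].to_json(outdir / "hmm_model.json", res["hmm_labels"])
    metrics = {
        k: res[k] for k in (
            "acr_recall", "acr_precision", "dacr_recall", "dacr_precision",
            "dacr_direction_accuracy", "deg_sensitivity",
            "maintained_fraction", "truth_maintained_fraction",
            "gene_state_accuracy", "cre_class_agreement",
            "responsive_cre_recovery", "responsive_cre_fdr",
            "triad_category_accuracy", "triad_response_accuracy", "runtime_s",
        ) if k in res
    }
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=1)
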