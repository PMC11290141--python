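"""Classification of (differential) ACRs into cis-regulatory element types.

Location: ACRs within 2 kb of a gene body are promoters; distal ACRs
split into K4-dACRs / nK4-dACRs by flanking H3K4me3.  A/R/M/U
modification labels come from flanking H3K27ac and H3K27me3 domains.
Distal elements get a nearest-TSS target gene, and homoeologous
nK4-dACRs are resolved across sub-genomes by target-homoeolog
correspondence plus local sequence alignment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GeneModel, Interval, IntervalIndex

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- location

def classify_location(
    acr: Interval, gene_index: IntervalIndex, promoter_dist: int = 2000
) -> str:
    """'promoter' iff the gap to the nearest gene body is <= promoter_dist."""
    d = gene_index.nearest_distance(acr)
    return "promoter" if d is not None and d <= promoter_dist else "distal"


def split_by_k4(
    acr: Interval, k4_index: IntervalIndex | None, flank: int = 500
) -> str:
    """'K4-dACR' iff the flank-extended ACR touches an H3K4me3 region."""
    if k4_index is None:
        return "nK4-dACR"
    return "K4-dACR" if k4_index.any_overlap(acr.expanded(flank)) else "nK4-dACR"


def label_modification(
    acr: Interval,
    k27ac_index: IntervalIndex,
    k27me3_index: IntervalIndex,
    flank: int = 500,
    k4_index: IntervalIndex | None = None,
    k4_counts_as_active: bool = True,
) -> str:
    """A/R/M/U from flank-extended overlap with H3K27ac / H3K27me3.

    An element near H3K4me3 but neither K27 mark has not "lacked the
    four modifications"; with ``k4_counts_as_active`` (default) it is
    reported as A rather than U.
    """
    ext = acr.expanded(flank)
    ac = k27ac_index.any_overlap(ext)
    me = k27me3_index.any_overlap(ext)
    if ac and me:
        return "M"
    if ac:
        return "A"
    if me:
        return "R"
    if k4_counts_as_active and k4_index is not None and k4_index.any_overlap(ext):
        return "A"
    return "U"


# ------------------------------------------------------------------ targets

def assign_target_gene(
    acr: Interval, genes: list[GeneModel]
) -> tuple[str | None, int | None]:
    """Nearest-TSS gene on the ACR's chromosome with signed distance.

    Distance is negative when the ACR lies upstream of the target's TSS
    (strand-aware), 0 when the TSS falls inside the ACR; distance ties
    break to the lexicographically smaller gene id.
    """
    best: tuple[int, str, GeneModel] | None = None
    for g in genes:
        if g.chrom != acr.chrom:
            continue
        if acr.start <= g.tss < acr.end:
            d = 0
        else:
            d = min(abs(g.tss - acr.start), abs(g.tss - (acr.end - 1)))
        key = (d, g.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (d, g.gene_id, g)
    if best is None:
        return None, None
    d, gid, g = best
    if d == 0:
        return gid, 0
    acr_upstream = (acr.end <= g.tss) if g.strand == "+" else (acr.start >= g.tss)
    return gid, -d if acr_upstream else d


# ----------------------------------------------------------------- homology

def local_alignment(seq1: str, seq2: str, match: int = 2,
                    mismatch: int = -2, gap: int = -3):
    """Best local (Smith-Waterman) alignment via Bio.Align.PairwiseAligner.

    Returns (score, identities, aligned_columns).
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    score = aligner.score(seq1, seq2)
    if score <= 0:
        return 0.0, 0, 0
    aln = aligner.align(seq1, seq2)[0]
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    return float(score), int(counts.identities), int(cols)


def sequences_homologous(
    seq1: str, seq2: str, min_id: float = 0.7, min_len: int = 50
) -> bool:
    _, ident, cols = local_alignment(seq1, seq2)
    return cols >= min_len and ident / cols >= min_id


def match_homoeologous_dacrs(
    dacrs: pd.DataFrame,
    sequences: dict[str, str] | None,
    triad_of_gene: dict[str, str],
    min_id: float = 0.7,
    min_len: int = 50,
) -> pd.Series:
    """Homology status per dACR from triad correspondence + alignment.

    `dacrs` needs columns acr_id, chrom, start, end, target_gene.  Two
    dACRs on different sub-genomes are homologous iff their targets are
    homoeologs of one triad AND (when sequence is available) their
    sequences align locally at >= min_id identity over >= min_len bp.
    """
    sg = dacrs.chrom.str[-1]
    triad = dacrs.target_gene.map(lambda g: triad_of_gene.get(g))
    partners: dict[str, set[str]] = {a: set() for a in dacrs.acr_id}
    for tid, group in dacrs.assign(sg=sg, triad=triad).groupby("triad"):
        if tid is None or len(group) < 2:
            continue
        for i, j in itertools.combinations(range(len(group)), 2):
            ri, rj = group.iloc[i], group.iloc[j]
            if ri.sg == rj.sg:
                continue
            if sequences is not None:
                s1 = sequences[ri.chrom][ri.start:ri.end]
                s2 = sequences[rj.chrom][rj.start:rj.end]
                if not sequences_homologous(s1, s2, min_id, min_len):
                    continue
            else:
                log.warning(
                    "no sequence for %s/%s; homology by target correspondence only",
                    ri.acr_id, rj.acr_id,
                )
            partners[ri.acr_id].add(rj.sg)
            partners[rj.acr_id].add(ri.sg)
    out = {}
    for r in dacrs.itertuples():
        p = partners[r.acr_id]
        if not p:
            out[r.acr_id] = "specific"
        else:
            members = ":".join(sorted(p | {r.chrom[-1]}))
            out[r.acr_id] = f"syntenic({members})"
    return pd.Series(out)


def dacr_gene_distance_shift(
    syntenic_pairs: pd.DataFrame, promoter_dist: int = 2000
) -> pd.DataFrame:
    """Per-pair |distance-to-gene| tuples with promoter-origin flags."""
    out = syntenic_pairs.copy()
    out["abs_dist_1"] = out.distance_1.abs()
    out["abs_dist_2"] = out.distance_2.abs()
    out["promoter_origin_1"] = out.abs_dist_1 <= promoter_dist
    out["promoter_origin_2"] = out.abs_dist_2 <= promoter_dist
    out["shift"] = (out.abs_dist_1 - out.abs_dist_2).abs()
    return out


# ------------------------------------------------------------ full annotation

@dataclass
class MarkRegions:
    """Peak/domain interval sets for the marks used in classification."""

    k4me3: list[Interval]
    k27ac: list[Interval]
    k27me3: list[Interval]
    k36me3: list[Interval] | None = None


def annotate_acrs(
    acrs: list[Interval],
    genes: list[GeneModel],
    marks: MarkRegions,
    responses: dict[str, str] | None = None,
    sequences: dict[str, str] | None = None,
    triad_of_gene: dict[str, str] | None = None,
    promoter_dist: int = 2000,
    flank: int = 500,
) -> pd.DataFrame:
    """One row per ACR: location class, A/R/M/U label, target, homology."""
    gene_bodies = IntervalIndex([g.interval for g in genes])
    k4_idx = IntervalIndex(marks.k4me3) if marks.k4me3 else None
    ac_idx = IntervalIndex(marks.k27ac)
    me_idx = IntervalIndex(marks.k27me3)
    rows = []
    for i, a in enumerate(acrs):
        acr_id = a.name if a.name not in (None, ".") else f"ACR{i:05d}"
        loc = classify_location(a, gene_bodies, promoter_dist)
        cre_class = loc if loc == "promoter" else split_by_k4(a, k4_idx, flank)
        mod = label_modification(a, ac_idx, me_idx, flank, k4_idx)
        target, dist = assign_target_gene(a, genes)
        rows.append(dict(
            acr_id=acr_id, chrom=a.chrom, start=a.start, end=a.end,
            cre_class=cre_class, mod_label=mod,
            target_gene=target, distance_to_target=dist,
            response=(responses or {}).get(acr_id, "stable"),
            subgenome=a.chrom[-1],
        ))
    df = pd.DataFrame(rows)
    df["homology"] = ""
    distal = df[df.cre_class != "promoter"]
    if len(distal) and triad_of_gene is not None:
        status = match_homoeologous_dacrs(distal, sequences, triad_of_gene)
        df.loc[distal.index, "homology"] = distal.acr_id.map(status).to_numpy()
    return df
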