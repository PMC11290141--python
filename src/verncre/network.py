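"""TF -> target regulatory network from motif hits in promoters and dACRs.

An edge connects a responsive transcription factor to a responsive
target gene whenever one of the TF's binding motifs hits a promoter or
distal element assigned to that gene.  Construction is a pure function
of its inputs; both raw (tf, target, element, motif) interactions and
the collapsed edge list are reported.
"""

from __future__ import annotations

import logging

import pandas as pd

from .motifs import MotifHit

log = logging.getLogger(__name__)


def build_network(
    responsive_genes: set[str],
    tf_annotation: pd.DataFrame,      # gene_id, family, motif_id
    motif_hits: list[MotifHit],       # element_id = ACR id
    cre_annotations: pd.DataFrame,    # acr_id, cre_class, target_gene
) -> pd.DataFrame:
    """Edge list with columns tf_gene_id, target_gene_id, element_id,
    element_class, motif_id, score (max over duplicate hits)."""
    motif_to_tfs: dict[str, list[str]] = {}
    for r in tf_annotation.itertuples():
        if r.gene_id in responsive_genes:
            motif_to_tfs.setdefault(r.motif_id, []).append(r.gene_id)
    elem = cre_annotations.set_index("acr_id")
    rows = []
    skipped = 0
    for h in motif_hits:
        tfs = motif_to_tfs.get(h.motif_id)
        if not tfs:
            skipped += 1
            continue
        if h.element_id not in elem.index:
            continue
        e = elem.loc[h.element_id]
        target = e.target_gene
        if target not in responsive_genes:
            continue
        for tf in tfs:
            rows.append(dict(
                tf_gene_id=tf, target_gene_id=target, element_id=h.element_id,
                element_class=e.cre_class, motif_id=h.motif_id, score=h.score,
            ))
    if skipped:
        log.info("skipped %d hits whose motif maps to no responsive TF", skipped)
    if not rows:
        return pd.DataFrame(columns=[
            "tf_gene_id", "target_gene_id", "element_id", "element_class",
            "motif_id", "score",
        ])
    df = pd.DataFrame(rows)
    df = (
        df.sort_values("score", ascending=False)
        .groupby(["tf_gene_id", "target_gene_id", "element_id", "motif_id"],
                 as_index=False)
        .agg(element_class=("element_class", "first"), score=("score", "max"))
        .sort_values(["tf_gene_id", "target_gene_id", "element_id", "motif_id"])
        .reset_index(drop=True)
    )
    return df


def network_summary(edges: pd.DataFrame) -> dict:
    """Edge/TF/target counts with degree tables."""
    if edges.empty:
        return dict(n_edges=0, n_tfs=0, n_targets=0,
                    out_degree=pd.Series(dtype=int), in_degree=pd.Series(dtype=int))
    return dict(
        n_edges=int(len(edges)),
        n_tfs=int(edges.tf_gene_id.nunique()),
        n_targets=int(edges.target_gene_id.nunique()),
        out_degree=edges.groupby("tf_gene_id").size(),
        in_degree=edges.groupby("target_gene_id").size(),
    )
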