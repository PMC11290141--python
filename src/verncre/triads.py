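"""Seven-category sub-genome balance classification of homoeolog triads.

A triad's (A, B, D) quantification is normalized to proportions and
assigned to the nearest of seven centroids in the homoeolog-bias
simplex: balanced (1/3,1/3,1/3), three dominant vertices and three
suppressed mid-edges.  The same geometry classifies response magnitudes
(|log2 fold-change| proportions) during vernalization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("Ba", "A", "B", "D", "a", "b", "d")
ALL_CATEGORIES = CATEGORIES + ("Un",)

CENTROIDS = {
    "Ba": np.array([1 / 3, 1 / 3, 1 / 3]),
    "A": np.array([1.0, 0.0, 0.0]),
    "B": np.array([0.0, 1.0, 0.0]),
    "D": np.array([0.0, 0.0, 1.0]),
    "a": np.array([0.0, 0.5, 0.5]),
    "b": np.array([0.5, 0.0, 0.5]),
    "d": np.array([0.5, 0.5, 0.0]),
}
_CENTROID_MAT = np.stack([CENTROIDS[c] for c in CATEGORIES])

UNBALANCED = {"A", "B", "D", "a", "b", "d"}


def classify_proportions(props: np.ndarray) -> np.ndarray:
    """Nearest-centroid category for each row of proportions; ties -> Ba."""
    props = np.atleast_2d(props)
    d2 = ((props[:, None, :] - _CENTROID_MAT[None, :, :]) ** 2).sum(axis=2)
    # exact ties resolve to the earliest category, with Ba listed first
    best = np.isclose(d2, d2.min(axis=1, keepdims=True), rtol=0, atol=1e-12)
    idx = best.argmax(axis=1)
    return np.array([CATEGORIES[i] for i in idx])


def classify_triad(
    v_a: float, v_b: float, v_d: float, expressed_min: float = 1.0
) -> str:
    """Balance category of one triad; Un if no homoeolog passes the gate."""
    v = np.array([v_a, v_b, v_d], dtype=float)
    if (v < 0).any():
        raise ValueError("triad values must be >= 0")
    if v.max() < expressed_min or v.sum() == 0:
        return "Un"
    return str(classify_proportions(v / v.sum())[0])


def classify_triads(
    values: pd.DataFrame, expressed_min: float = 1.0
) -> pd.Series:
    """Vectorized categories for a (triad x [A,B,D]) value frame."""
    v = values[["A", "B", "D"]].to_numpy(dtype=float)
    if (v < 0).any():
        raise ValueError("triad values must be >= 0")
    cats = np.full(v.shape[0], "Un", dtype=object)
    ok = (v.max(axis=1) >= expressed_min) & (v.sum(axis=1) > 0)
    if ok.any():
        props = v[ok] / v[ok].sum(axis=1, keepdims=True)
        cats[ok] = classify_proportions(props)
    return pd.Series(cats, index=values.index)


def classify_triad_response(
    before: np.ndarray,
    after: np.ndarray,
    respond_min_fold: float = 2.0,
    pseudo: float = 1.0,
) -> str:
    """Response-balance category from |log2FC| magnitudes.

    "NR" when no homoeolog reaches the fold gate; otherwise the
    magnitudes are normalized and nearest-centroid classified (capital
    letter = that sub-genome dominates the response; lower-case = it
    fails to respond while the other two do; Ba = balanced response).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if (before < 0).any() or (after < 0).any():
        raise ValueError("negative quantifications")
    m = np.abs(np.log2((after + pseudo) / (before + pseudo)))
    if m.max() < np.log2(respond_min_fold):
        return "NR"
    return str(classify_proportions(m / m.sum())[0])


def classify_triad_responses(
    before: pd.DataFrame, after: pd.DataFrame,
    respond_min_fold: float = 2.0, pseudo: float = 1.0,
) -> pd.Series:
    out = {
        tid: classify_triad_response(
            before.loc[tid, ["A", "B", "D"]].to_numpy(),
            after.loc[tid, ["A", "B", "D"]].to_numpy(),
            respond_min_fold, pseudo,
        )
        for tid in before.index
    }
    return pd.Series(out)


def balance_transitions(
    cats_before: pd.Series, cats_after: pd.Series
) -> pd.DataFrame:
    """8x8 (before x after) category transition counts, Un included."""
    missing = set(cats_before.index) ^ set(cats_after.index)
    if missing:
        raise ValueError(f"triad universes differ: {sorted(missing)[:5]}")
    cats = list(ALL_CATEGORIES)
    extra = sorted(
        (set(cats_before.unique()) | set(cats_after.unique())) - set(cats)
    )
    cats = cats + extra
    table = pd.DataFrame(0, index=cats, columns=cats)
    for tid in cats_before.index:
        table.loc[cats_before[tid], cats_after[tid]] += 1
    return table


def unbalanced_association(
    expr_cats: pd.Series, layer_cats: dict[str, pd.Series]
) -> pd.DataFrame:
    """Cross-layer association of unbalanced responses.

    For each epigenomic layer: the fraction of unbalanced-expression
    triads that are also unbalanced in the layer; the fraction of
    unbalanced-expression triads within the layer-balanced vs
    layer-unbalanced groups; and a 2x2 Fisher exact p. Triads that are
    NR/Un in either member of a comparison are excluded from it.
    """
    rows = []
    for layer, cats in layer_cats.items():
        common = expr_cats.index.intersection(cats.index)
        e = expr_cats.loc[common]
        l = cats.loc[common]
        use = e.isin(CATEGORIES) & l.isin(CATEGORIES)
        e, l = e[use], l[use]
        e_unb = e.isin(UNBALANCED)
        l_unb = l.isin(UNBALANCED)
        n11 = int((e_unb & l_unb).sum())
        n10 = int((e_unb & ~l_unb).sum())
        n01 = int((~e_unb & l_unb).sum())
        n00 = int((~e_unb & ~l_unb).sum())
        frac_layer_unb = n11 / (n11 + n10) if (n11 + n10) else np.nan
        frac_expr_in_unb = n11 / (n11 + n01) if (n11 + n01) else np.nan
        frac_expr_in_bal = n10 / (n10 + n00) if (n10 + n00) else np.nan
        _, p = stats.fisher_exact([[n11, n10], [n01, n00]])
        rows.append(dict(
            layer=layer, n=int(use.sum()),
            frac_unbalanced_layer_given_unbalanced_expr=frac_layer_unb,
            frac_unbalanced_expr_in_layer_unbalanced=frac_expr_in_unb,
            frac_unbalanced_expr_in_layer_balanced=frac_expr_in_bal,
            fisher_p=float(p),
        ))
    return pd.DataFrame(rows).set_index("layer")
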