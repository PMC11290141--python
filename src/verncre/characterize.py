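"""Sequence and annotation characterization of regulatory elements:
GC content, SNP density meta-profiles, shuffle-null overlap enrichment,
TE-superfamily overlap and motif enrichment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Interval, IntervalIndex
from .motifs import MotifHit, PWM, scan_motifs  # noqa: F401  (re-exported surface)
from .stats import bh_fdr


# --------------------------------------------------------------- GC content

def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T); ambiguous bases excluded from the denominator."""
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (s.count("G") + s.count("C")) / acgt


def gc_group_comparison(
    element_seqs: list[str], background_seqs: list[str]
) -> dict:
    """Element vs background GC with a Mann-Whitney U p-value."""
    a = np.array([gc_content(s) for s in element_seqs])
    b = np.array([gc_content(s) for s in background_seqs])
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return dict(element_mean=float(a.mean()), background_mean=float(b.mean()),
                mannwhitney_u=float(u), p=float(p))


def sample_background_intervals(
    elements: list[Interval],
    chrom_sizes: dict[str, int],
    rng: np.random.Generator,
    exclude: IntervalIndex | None = None,
) -> list[Interval]:
    """Length-matched random intervals on each element's own chromosome."""
    out = []
    for iv in elements:
        size = chrom_sizes[iv.chrom]
        for _ in range(100):
            s = int(rng.integers(0, size - len(iv)))
            cand = Interval(iv.chrom, s, s + len(iv))
            if exclude is None or not exclude.any_overlap(cand):
                out.append(cand)
                break
        else:
            out.append(cand)
    return out


# --------------------------------------------------------------- SNP profile

def snp_density_profile(
    elements: list[Interval],
    snps: list[Interval],
    flank: int = 2000,
    bin_size: int = 100,
    body_bins: int = 10,
) -> pd.DataFrame:
    """Element-centered meta-profile of SNPs per bp.

    Flanks use fixed `bin_size` bins; the element body is rescaled onto
    `body_bins` bins so elements of different lengths stack.
    """
    n_flank = flank // bin_size
    n_tot = 2 * n_flank + body_bins
    acc = np.zeros(n_tot)
    bp = np.zeros(n_tot)
    pos_by_chrom: dict[str, np.ndarray] = {}
    for s in snps:
        pos_by_chrom.setdefault(s.chrom, []).append(s.start)  # type: ignore[arg-type]
    pos_by_chrom = {c: np.sort(np.array(v)) for c, v in pos_by_chrom.items()}
    for iv in elements:
        pos = pos_by_chrom.get(iv.chrom, np.empty(0, dtype=int))
        L = len(iv)
        # left flank
        for b in range(n_flank):
            lo = iv.start - flank + b * bin_size
            hi = lo + bin_size
            acc[b] += np.searchsorted(pos, hi) - np.searchsorted(pos, lo)
            bp[b] += bin_size
        # body, rescaled
        edges = iv.start + np.round(np.linspace(0, L, body_bins + 1)).astype(int)
        for b in range(body_bins):
            lo, hi = edges[b], edges[b + 1]
            acc[n_flank + b] += np.searchsorted(pos, hi) - np.searchsorted(pos, lo)
            bp[n_flank + b] += hi - lo
        # right flank
        for b in range(n_flank):
            lo = iv.end + b * bin_size
            hi = lo + bin_size
            acc[n_flank + body_bins + b] += np.searchsorted(pos, hi) - np.searchsorted(pos, lo)
            bp[n_flank + body_bins + b] += bin_size
    dens = np.divide(acc, bp, out=np.zeros(n_tot), where=bp > 0)
    region = (["flank_left"] * n_flank + ["body"] * body_bins
              + ["flank_right"] * n_flank)
    return pd.DataFrame(dict(bin=np.arange(n_tot), region=region, density=dens))


def body_flank_ratio(profile: pd.DataFrame) -> float:
    body = profile.loc[profile.region == "body", "density"].mean()
    flank = profile.loc[profile.region != "body", "density"].mean()
    return float(body / flank) if flank > 0 else float("nan")


# ----------------------------------------------------- shuffle-null overlap

@dataclass
class EnrichmentResult:
    observed_pct: float
    null_mean: float
    null_sd: float
    z: float
    empirical_p: float
    n_shuffles: int
    null_values: np.ndarray


def overlap_enrichment(
    elements: list[Interval],
    signals: list[Interval],
    chrom_sizes: dict[str, int],
    window: int = 1000,
    n_shuffles: int = 1000,
    seed: int = 0,
    exclude: IntervalIndex | None = None,
) -> EnrichmentResult:
    """Observed % of elements with a signal within `window`, against a
    null of length-matched elements placed uniformly on the same
    chromosome (1 + count)/(n + 1) empirical p."""
    import logging

    if n_shuffles < 100:
        logging.getLogger(__name__).warning(
            "n_shuffles=%d is low; empirical p resolution is coarse", n_shuffles
        )
    sig_idx = IntervalIndex(signals)

    def pct(ivs: list[Interval]) -> float:
        hit = sum(
            1 for iv in ivs
            if sig_idx.any_overlap(iv.expanded(window, chrom_sizes[iv.chrom]))
        )
        return 100.0 * hit / len(ivs) if ivs else 0.0

    observed = pct(elements)
    rng = np.random.default_rng(seed)
    null = np.array([
        pct(sample_background_intervals(elements, chrom_sizes, rng, exclude))
        for _ in range(n_shuffles)
    ])
    sd = float(null.std(ddof=1)) if n_shuffles > 1 else 0.0
    z = (observed - null.mean()) / sd if sd > 0 else float("nan")
    p = (1 + int((null >= observed).sum())) / (n_shuffles + 1)
    return EnrichmentResult(observed, float(null.mean()), sd, float(z), p,
                            n_shuffles, null)


# ---------------------------------------------------------------- TE overlap

def te_overlap(
    elements: list[Interval],
    tes: list[Interval],
    denominators: dict[str, list[Interval]] | None = None,
) -> pd.DataFrame:
    """Fraction of elements overlapping >= 1 bp of each TE superfamily.

    The TE name field carries the superfamily code; unknown codes form
    their own category.  Optional denominator sets give ratio columns.
    """
    fams = sorted({t.name for t in tes})
    idx = {f: IntervalIndex([t for t in tes if t.name == f]) for f in fams}

    def fractions(ivs: list[Interval]) -> dict[str, float]:
        if not ivs:
            return {f: 0.0 for f in fams}
        return {
            f: sum(1 for iv in ivs if idx[f].any_overlap(iv)) / len(ivs)
            for f in fams
        }

    out = pd.DataFrame({"elements": fractions(elements)})
    for name, denom in (denominators or {}).items():
        d = fractions(denom)
        out[name] = pd.Series(d)
        out[f"ratio_vs_{name}"] = out["elements"] / out[name].replace(0, np.nan)
    out.index.name = "superfamily"
    return out


# ----------------------------------------------------------- motif enrichment

def motif_enrichment(
    target_seqs: dict[str, str],
    background_seqs: dict[str, str],
    pwms: list[PWM],
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Per-motif fold enrichment of >=1-hit element fractions with a
    hypergeometric p; depletion (fold < 1) is tested on the lower tail."""
    t_hits = scan_motifs(target_seqs, pwms, p_threshold)
    b_hits = scan_motifs(background_seqs, pwms, p_threshold)
    rows = []
    for pwm in pwms:
        t_with = len({h.element_id for h in t_hits if h.motif_id == pwm.motif_id})
        b_with = len({h.element_id for h in b_hits if h.motif_id == pwm.motif_id})
        nt, nb = len(target_seqs), len(background_seqs)
        ft = t_with / nt if nt else 0.0
        fb = b_with / nb if nb else 0.0
        fold = ft / fb if fb > 0 else (np.inf if ft > 0 else np.nan)
        # hypergeometric: draws=nt from population nt+nb with t_with+b_with successes
        M, n, N = nt + nb, t_with + b_with, nt
        p_enr = float(stats.hypergeom.sf(t_with - 1, M, n, N))
        p_dep = float(stats.hypergeom.cdf(t_with, M, n, N))
        p = min(1.0, 2.0 * min(p_enr, p_dep))
        rows.append(dict(
            motif_id=pwm.motif_id, n_target=nt, n_background=nb,
            target_with_hit=t_with, background_with_hit=b_with,
            target_frac=ft, background_frac=fb, fold=fold,
            p=p, p_enriched=p_enr, p_depleted=p_dep,
            infinite_fold=bool(fb == 0 and ft > 0),
        ))
    df = pd.DataFrame(rows).set_index("motif_id")
    df["fdr"] = bh_fdr(df.p.to_numpy())
    return df
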