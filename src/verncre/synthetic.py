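"""Miniature allohexaploid genome and assay simulator with known ground truth.

The generator emulates a vernalization experiment on a wheat-like genome:
three sub-genomes (A, B, D) carrying homoeologous gene triads, planted
promoter and distal accessible chromatin regions (ACRs), four histone-mark
domains consistent with activated/repressed/mixed/unmodified chromatin
states, negative-binomially distributed Tn5 integration-site (TIS) and
RNA counts over two conditions ("before"/"after" cold treatment), SNP
depletion inside cis-regulatory elements, GWAS signals near responsive
elements, biased transposable-element placement and planted transcription
factor binding motifs.

Every random draw flows from ``SyntheticConfig.seed`` through named
substreams, so a fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GeneModel, Interval, merge_intervals
from .genomio import (
    Track,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_gff3,
)
from .motifs import PWM

CONDITIONS = ("before", "after")
SUBGENOMES = ("A", "B", "D")
STATES = ("activated", "repressed", "mixed", "unmodified")
MARKS = ("H3K4me3", "H3K27ac", "H3K36me3", "H3K27me3")
ACTIVE_MARKS = ("H3K4me3", "H3K27ac", "H3K36me3")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

GENE_LEN = 1200
GENE_OFFSET = 3600          # gene start within its slot
ACR_WIDTH = 400
PROMOTER_ACR_GAP = 200      # promoter ACR sits [TSS-600, TSS-200)


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study-design parameters of the simulated vernalization experiment."""

    n_chroms_per_subgenome: int = 1
    chrom_length: int = 2_000_000
    n_triads: int = 300
    n_singletons: int = 60
    acr_per_gene: int = 2            # 1 promoter ACR + (acr_per_gene-1) distal
    frac_responsive_acrs: float = 0.3
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    library_size: float = 2e6
    replicates: int = 2
    enrichment: float = 8.0          # ACR TIS rate over background
    frac_syntenic_dacrs: float = 0.6
    frac_k4_dacrs: float = 0.4
    snp_rate: float = 0.004          # SNPs per bp outside elements
    snp_depletion: float = 3.0
    n_gwas: int = 200
    frac_gwas_near_cre: float = 0.5
    n_te_per_chrom: int = 300
    frac_te_on_specific: float = 0.5
    motif_frac_responsive: float = 0.8
    motif_frac_background: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_chroms_per_subgenome", "n_triads", "n_singletons",
                     "acr_per_gene", "replicates"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("frac_responsive_acrs", "frac_syntenic_dacrs",
                     "frac_k4_dacrs", "frac_gwas_near_cre",
                     "frac_te_on_specific", "motif_frac_responsive",
                     "motif_frac_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.chrom_length < 50_000:
            raise ConfigError("chrom_length must be >= 50000")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        genes_per_chrom = self._genes_per_chrom()
        slot = self.chrom_length // (genes_per_chrom + 2)
        if slot < 6210:
            raise ConfigError(
                "chrom_length too small for the gene count: need "
                f">= {6210 * (genes_per_chrom + 2)} bp for "
                f"{genes_per_chrom} genes per chromosome"
            )

    def _genes_per_chrom(self) -> int:
        n_chr = self.n_chroms_per_subgenome
        singleton_slots = -(-self.n_singletons // 3)
        return -(-(self.n_triads + singleton_slots) // n_chr)

    def rng(self, *stream: object) -> np.random.Generator:
        # stable cross-process substream keys (built-in hash() is salted)
        key = [
            int.from_bytes(hashlib.blake2s(str(s).encode(), digest_size=4).digest(),
                           "big")
            for s in stream
        ]
        return np.random.default_rng([self.seed % (2**31), *key])


@dataclass
class GroundTruth:
    """Planted truth for every downstream stage."""

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame       # gene_id, chrom, start, end, strand, triad_id,
                              # subgenome, responsive, direction, state_before,
                              # state_after, mean_before, mean_after, is_tf
    acrs: pd.DataFrame        # acr_id, chrom, start, end, cre_class, mod_label,
                              # response, log2fc, target_gene, homology, has_motif
    triads: pd.DataFrame      # triad_id, gene_A, gene_B, gene_D, category,
                              # response_cat
    mark_domains: dict = field(default_factory=dict)   # (mark, cond) -> [Interval]
    state_track: dict = field(default_factory=dict)    # cond -> {chrom: int8/bin}
    motif_instances: list = field(default_factory=list)  # (acr_id, offset)
    snps: list = field(default_factory=list)
    gwas: list = field(default_factory=list)
    tes: list = field(default_factory=list)
    pwms: list = field(default_factory=list)
    tf_table: pd.DataFrame | None = None

    def acr_intervals(self, classes: set[str] | None = None) -> list[Interval]:
        rows = self.acrs
        if classes is not None:
            rows = rows[rows.cre_class.isin(classes)]
        return [
            Interval(r.chrom, int(r.start), int(r.end), name=r.acr_id)
            for r in rows.itertuples()
        ]

    def responsive_acrs(self) -> pd.DataFrame:
        return self.acrs[self.acrs.response != "stable"]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.acrs.to_csv(outdir / "truth_acrs.tsv", sep="\t", index=False)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.triads.to_csv(outdir / "truth_triads.tsv", sep="\t", index=False)

    @staticmethod
    def read_tables(outdir) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        outdir = Path(outdir)
        return (
            pd.read_csv(outdir / "truth_acrs.tsv", sep="\t"),
            pd.read_csv(outdir / "truth_genes.tsv", sep="\t"),
            pd.read_csv(outdir / "truth_triads.tsv", sep="\t", dtype={"triad_id": str}),
        )


@dataclass
class SyntheticGenome:
    config: SyntheticConfig
    sequences: dict[str, np.ndarray]    # uint8 ASCII arrays
    genes: list[GeneModel]
    triad_table: pd.DataFrame
    truth: GroundTruth

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def sequence_str(self, chrom: str, start: int = 0, end: int | None = None) -> str:
        arr = self.sequences[chrom]
        return arr[start : end if end is not None else len(arr)].tobytes().decode()

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "genome.fa", {c: self.sequence_str(c) for c in self.sequences})
        write_gff3(outdir / "genes.gff3", self.genes)
        self.triad_table.to_csv(outdir / "triads.tsv", sep="\t", index=False)
        self.truth.write(outdir)


# ----------------------------------------------------------------- sequences

def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.45) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    n_mut = rng.binomial(len(seq), rate)
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    shift = rng.integers(1, 4, size=n_mut)
    idx = np.searchsorted(_BASES, out[pos])
    out[pos] = _BASES[(idx + shift) % 4]
    return out


def _plant(seq_arr: np.ndarray, start: int, payload: bytes) -> None:
    seq_arr[start : start + len(payload)] = np.frombuffer(payload, dtype=np.uint8)


# ------------------------------------------------------------------ the PWMs

SPL_CONSENSUS = "TCGTACGA"      # GTAC-core SPL/SBP-like motif
DECOY_CONSENSI = {
    "MYB_like": "CAACTGAC",
    "WRKY_like": "TTTGACCA",
    "Dof_like": "CAAAGTGC",
}


def default_pwms() -> list[PWM]:
    pwms = [PWM.from_consensus("SPL_like", SPL_CONSENSUS, p=0.9)]
    for name, cons in DECOY_CONSENSI.items():
        pwms.append(PWM.from_consensus(name, cons, p=0.9))
    return pwms


# ------------------------------------------------------------------- genome

def generate_genome(config: SyntheticConfig) -> SyntheticGenome:
    """Lay out genes, triads and planted ACRs and synthesize sequences."""
    config.validate()
    n_chr = config.n_chroms_per_subgenome
    n_singleton_slots = -(-config.n_singletons // 3)
    genes_per_chrom = config._genes_per_chrom()
    slot = config.chrom_length // (genes_per_chrom + 2)

    chrom_sizes = {
        f"chr{i + 1}{sg}": config.chrom_length
        for sg in SUBGENOMES
        for i in range(n_chr)
    }
    seq_rng = config.rng("sequence")
    sequences = {c: _random_seq(config.rng("chromseq", c), config.chrom_length)
                 for c in chrom_sizes}

    layout_rng = config.rng("layout")
    genes: list[GeneModel] = []
    gene_rows = []
    acr_rows = []
    triad_rows = []
    motif_instances: list[tuple[str, int]] = []

    # triad-level draws shared across the three homoeologs
    n_units = config.n_triads + n_singleton_slots  # gene slots per sub-genome
    strand_draw = layout_rng.choice(["+", "-"], size=n_units)
    base_mean = 2.0 ** layout_rng.normal(np.log2(100.0), 1.0, size=n_units)
    cat_choices = ["Ba", "A", "B", "D", "a", "b", "d", "Un"]
    cat_p = [0.64, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.06]
    triad_cat = layout_rng.choice(cat_choices, size=config.n_triads, p=cat_p)
    responsive_draw = layout_rng.random(n_units) < config.frac_responsive_acrs
    # exact induced/repressed balance keeps expected library mass equal
    # across conditions under the symmetric fold scheme
    resp_idx = np.flatnonzero(responsive_draw)
    direction = np.full(n_units, "stable", dtype=object)
    direction[resp_idx[0::2]] = "induced"
    direction[resp_idx[1::2]] = "repressed"
    # which sub-genomes respond: balanced (all three) or single-sub-genome
    resp_mode = layout_rng.choice(["balanced", "single"], size=n_units, p=[2 / 3, 1 / 3])
    resp_sg = layout_rng.choice(list(SUBGENOMES), size=n_units)
    syntenic_draw = layout_rng.random(n_units) < config.frac_syntenic_dacrs
    specific_sg = layout_rng.choice(list(SUBGENOMES), size=n_units)
    k4_draw = layout_rng.random((n_units, max(1, config.acr_per_gene - 1))) \
        < config.frac_k4_dacrs
    modlabel_draw = layout_rng.choice(
        ["A", "R", "M", "U"], size=(n_units, max(1, config.acr_per_gene - 1)),
        p=[0.4, 0.25, 0.1, 0.25],
    )
    mixed_draw = layout_rng.random(n_units) < 0.10
    repressed_draw = layout_rng.random(n_units) < 0.5
    dacr_jitter = layout_rng.integers(0, 200, size=n_units)

    centroids = {
        "Ba": (1 / 3, 1 / 3, 1 / 3),
        "A": (1.0, 0.0, 0.0), "B": (0.0, 1.0, 0.0), "D": (0.0, 0.0, 1.0),
        "a": (0.0, 0.5, 0.5), "b": (0.5, 0.0, 0.5), "d": (0.5, 0.5, 0.0),
    }

    half_fold = 2.0 ** (config.planted_log2fc / 2.0)

    def unit_chrom_slot(unit: int) -> tuple[int, int]:
        return unit % n_chr, unit // n_chr

    for unit in range(n_units):
        is_triad = unit < config.n_triads
        chrom_i, slot_j = unit_chrom_slot(unit)
        g0 = (slot_j + 1) * slot + GENE_OFFSET
        strand = str(strand_draw[unit])
        # shared gene sequence for homoeolog identity >= 85%
        gene_seq = _random_seq(config.rng("geneseq", unit), GENE_LEN)
        if is_triad:
            members = SUBGENOMES
        else:
            placed = (unit - config.n_triads) * 3
            members = SUBGENOMES[: min(3, config.n_singletons - placed)]
            if not members:
                continue
        triad_id = f"triad{unit:04d}" if is_triad else None
        category = triad_cat[unit] if is_triad else "Ba"
        props = centroids.get(category, centroids["Ba"])

        # expression means per member; Un triads sit below the TPM gate
        if category == "Un":
            member_means = {sg: 0.02 for sg in SUBGENOMES}
        else:
            member_means = {
                sg: 3.0 * base_mean[unit] * props[k]
                for k, sg in enumerate(SUBGENOMES)
            }

        resp_members = set()
        if direction[unit] != "stable" and category != "Un":
            resp_members = (
                set(members) if resp_mode[unit] == "balanced" or not is_triad
                else {resp_sg[unit]}
            )
            resp_members = {sg for sg in resp_members if member_means[sg] >= 1.0}

        member_gene_ids = {}
        member_mb, member_ma = {}, {}
        for sg in members:
            chrom = f"chr{chrom_i + 1}{sg}"
            gid = f"Gene{unit:04d}{sg}"
            member_gene_ids[sg] = gid
            if is_triad:
                seq = _mutate(config.rng("genemut", unit, sg), gene_seq, 0.04)
            else:
                seq = _random_seq(config.rng("geneseq", unit, sg), GENE_LEN)
            _plant(sequences[chrom], g0, seq.tobytes())
            iv = Interval(chrom, g0, g0 + GENE_LEN, name=gid, strand=strand)
            genes.append(GeneModel(gid, iv, triad_id))

            mean_b = member_means[sg]
            responds = sg in resp_members
            if responds and direction[unit] == "induced":
                mean_b, mean_a = mean_b / half_fold, member_means[sg] * half_fold
            elif responds and direction[unit] == "repressed":
                mean_b, mean_a = mean_b * half_fold, member_means[sg] / half_fold
            else:
                mean_a = mean_b

            # chromatin states: responsive genes flip between U and A;
            # stable genes keep a coherent state in both conditions
            if responds and direction[unit] == "induced":
                s_before, s_after = "unmodified", "activated"
            elif responds and direction[unit] == "repressed":
                s_before, s_after = "activated", "unmodified"
            elif category == "Un" or max(mean_b, mean_a) < 1:
                s = "repressed" if repressed_draw[unit] else "unmodified"
                s_before = s_after = s
            else:
                s_before = s_after = "mixed" if mixed_draw[unit] else "activated"

            member_mb[sg], member_ma[sg] = mean_b, mean_a
            gene_rows.append(dict(
                gene_id=gid, chrom=chrom, start=g0, end=g0 + GENE_LEN,
                strand=strand, triad_id=triad_id or "", subgenome=sg,
                responsive=responds,
                direction=direction[unit] if responds else "stable",
                state_before=s_before, state_after=s_after,
                mean_before=mean_b, mean_after=mean_a, is_tf=False,
            ))

            # promoter ACR, one per gene
            if strand == "+":
                p_start = g0 - PROMOTER_ACR_GAP - ACR_WIDTH
            else:
                p_start = g0 + GENE_LEN + PROMOTER_ACR_GAP
            mod = {"activated": "A", "repressed": "R",
                   "mixed": "M", "unmodified": "U"}[s_before]
            acr_rows.append(dict(
                acr_id=f"pACR{unit:04d}{sg}", chrom=chrom,
                start=p_start, end=p_start + ACR_WIDTH, cre_class="promoter",
                mod_label=mod,
                response=direction[unit] if responds else "stable",
                log2fc=(config.planted_log2fc if responds and direction[unit] == "induced"
                        else -config.planted_log2fc if responds else 0.0),
                target_gene=gid, homology="", has_motif=False,
            ))

        # distal ACRs: syntenic across the triad or sub-genome specific
        n_distal = config.acr_per_gene - 1
        if n_distal >= 1 and is_triad:
            d_members = list(SUBGENOMES) if syntenic_draw[unit] else [str(specific_sg[unit])]
            homology = (
                "syntenic(A:B:D)" if syntenic_draw[unit] else "specific"
            )
            for d in range(n_distal):
                cre_seq = _random_seq(config.rng("creseq", unit, d), ACR_WIDTH, gc=0.55)
                # window between prev gene end + 2kb and this gene - 2kb,
                # with ~200 bp margin so called boundaries cannot cross
                # the promoter-distance rule
                prev_end = (slot_j + 1) * slot - slot + GENE_OFFSET + GENE_LEN
                d_start = prev_end + 2205 + int(dacr_jitter[unit])
                for sg in d_members:
                    chrom = f"chr{chrom_i + 1}{sg}"
                    acr_id = f"dACR{unit:04d}{sg}_{d}"
                    seq = _mutate(config.rng("cremut", unit, d, sg), cre_seq, 0.03)
                    responds = sg in resp_members
                    plant_motif_rng = config.rng("motif", unit, d, sg)
                    frac = (config.motif_frac_responsive if responds
                            else config.motif_frac_background)
                    has_motif = bool(plant_motif_rng.random() < frac)
                    _plant(sequences[chrom], d_start, seq.tobytes())
                    if has_motif:
                        off = 100 + int(plant_motif_rng.integers(0, ACR_WIDTH - 220))
                        _plant(sequences[chrom], d_start + off,
                               SPL_CONSENSUS.encode())
                        motif_instances.append((acr_id, off))
                    acr_rows.append(dict(
                        acr_id=acr_id, chrom=chrom,
                        start=d_start, end=d_start + ACR_WIDTH,
                        cre_class="K4-dACR" if k4_draw[unit, d] else "nK4-dACR",
                        mod_label=str(modlabel_draw[unit, d]),
                        response=direction[unit] if responds else "stable",
                        log2fc=(config.planted_log2fc if responds and direction[unit] == "induced"
                                else -config.planted_log2fc if responds else 0.0),
                        target_gene="", homology=homology, has_motif=has_motif,
                    ))

        if is_triad:
            # response category implied by the generative means (the
            # |log2FC| magnitude simplex with pseudo-count 1)
            mb = np.array([member_mb[sg] for sg in SUBGENOMES])
            ma = np.array([member_ma[sg] for sg in SUBGENOMES])
            m = np.abs(np.log2((ma + 1.0) / (mb + 1.0)))
            if m.max() < 1.0:
                resp_cat = "NR"
            else:
                props = m / m.sum()
                cents = {"Ba": (1/3, 1/3, 1/3), "A": (1, 0, 0), "B": (0, 1, 0),
                         "D": (0, 0, 1), "a": (0, .5, .5), "b": (.5, 0, .5),
                         "d": (.5, .5, 0)}
                resp_cat = min(
                    cents, key=lambda c: float(((props - np.array(cents[c]))**2).sum())
                )
            triad_rows.append(dict(
                triad_id=triad_id,
                gene_A=member_gene_ids["A"], gene_B=member_gene_ids["B"],
                gene_D=member_gene_ids["D"],
                category=category, response_cat=resp_cat,
            ))

    gene_df = pd.DataFrame(gene_rows)
    acr_df = pd.DataFrame(acr_rows)
    triad_df = pd.DataFrame(triad_rows)

    # distal ACR true targets: nearest TSS by a direct scan
    gene_df_sorted = gene_df.sort_values(["chrom", "start"])
    tss_by_chrom = {
        c: (sub.apply(lambda r: r.start if r.strand == "+" else r.end, axis=1).to_numpy(),
            sub.gene_id.to_numpy())
        for c, sub in gene_df_sorted.groupby("chrom")
    }
    targets = []
    for r in acr_df.itertuples():
        if r.target_gene:
            targets.append(r.target_gene)
            continue
        tss, gids = tss_by_chrom[r.chrom]
        mid_dist = np.minimum(np.abs(tss - r.start), np.abs(tss - r.end))
        inside = (tss >= r.start) & (tss < r.end)
        mid_dist[inside] = 0
        best = np.min(mid_dist)
        cand = sorted(gids[mid_dist == best])
        targets.append(cand[0])
    acr_df["target_gene"] = targets

    truth = GroundTruth(
        chrom_sizes=chrom_sizes, genes=gene_df, acrs=acr_df, triads=triad_df,
        motif_instances=motif_instances,
    )
    _build_mark_domains(truth)
    _build_state_track(truth)
    truth.pwms = default_pwms()
    truth.tf_table = _designate_tfs(gene_df)
    return SyntheticGenome(config, sequences, genes, triad_df, truth)


def _designate_tfs(gene_df: pd.DataFrame) -> pd.DataFrame:
    """Mark a handful of responsive genes as SPL-family TFs plus decoy families."""
    resp = gene_df[gene_df.responsive].gene_id.tolist()
    stable = gene_df[~gene_df.responsive].gene_id.tolist()
    rows = []
    for gid in resp[:6]:
        rows.append(dict(gene_id=gid, family="SPL", motif_id="SPL_like"))
    for gid, fam, mot in zip(stable[:3], ["MYB", "WRKY", "Dof"],
                             ["MYB_like", "WRKY_like", "Dof_like"]):
        rows.append(dict(gene_id=gid, family=fam, motif_id=mot))
    gene_df.loc[gene_df.gene_id.isin([r["gene_id"] for r in rows]), "is_tf"] = True
    return pd.DataFrame(rows)


def _build_mark_domains(truth: GroundTruth) -> None:
    """Mark domains driven by gene states (condition-specific) and by the
    planted K4/modification labels of distal elements (static)."""
    for cond in CONDITIONS:
        dom: dict[str, list[Interval]] = {m: [] for m in MARKS}
        col = f"state_{cond}"
        for g in truth.genes.itertuples():
            state = getattr(g, col)
            if g.strand == "+":
                tss = g.start
                k4 = (max(0, tss - 400), tss + 600)
            else:
                tss = g.end
                k4 = (tss - 600, tss + 400)
            if state in ("activated", "mixed"):
                dom["H3K4me3"].append(Interval(g.chrom, *k4))
                dom["H3K27ac"].append(Interval(g.chrom, max(0, g.start - 500), g.end + 500))
                dom["H3K36me3"].append(Interval(g.chrom, g.start, g.end))
            if state in ("repressed", "mixed"):
                dom["H3K27me3"].append(Interval(g.chrom, max(0, g.start - 1000), g.end + 1000))
        for r in truth.acrs.itertuples():
            if r.cre_class == "promoter":
                continue
            if r.cre_class == "K4-dACR":
                dom["H3K4me3"].append(Interval(r.chrom, max(0, r.start - 300), r.end + 300))
            if r.mod_label in ("A", "M"):
                dom["H3K27ac"].append(Interval(r.chrom, max(0, r.start - 200), r.end + 200))
            if r.mod_label in ("R", "M"):
                dom["H3K27me3"].append(Interval(r.chrom, max(0, r.start - 200), r.end + 200))
        for m in MARKS:
            truth.mark_domains[(m, cond)] = merge_intervals(dom[m], 0)


STATE_CODE = {s: i for i, s in enumerate(STATES)}


def _build_state_track(truth: GroundTruth, bin_size: int = 200) -> None:
    mod_to_state = {"A": "activated", "R": "repressed", "M": "mixed", "U": "unmodified"}
    for cond in CONDITIONS:
        track = {
            c: np.full(-(-n // bin_size), STATE_CODE["unmodified"], dtype=np.int8)
            for c, n in truth.chrom_sizes.items()
        }
        col = f"state_{cond}"
        for g in truth.genes.itertuples():
            s, e = (g.start - 2000, g.end) if g.strand == "+" else (g.start, g.end + 2000)
            b0, b1 = max(0, s) // bin_size, -(-e // bin_size)
            track[g.chrom][b0:b1] = STATE_CODE[getattr(g, col)]
        for r in truth.acrs.itertuples():
            if r.cre_class == "promoter":
                continue
            b0, b1 = r.start // bin_size, -(-r.end // bin_size)
            track[r.chrom][b0:b1] = STATE_CODE[mod_to_state[r.mod_label]]
        truth.state_track[cond] = track


# ----------------------------------------------------------------- TIS model

def _tis_rates(truth: GroundTruth, config: SyntheticConfig, condition: str) -> Track:
    """Per-base Poisson rates, scaled so the expected genome-wide total is
    the library size (one shared scale for both conditions so planted
    fold-changes stay exact)."""
    half = 2.0 ** (config.planted_log2fc / 2.0)
    rates = {c: np.ones(n, dtype=np.float64) for c, n in truth.chrom_sizes.items()}
    for r in truth.acrs.itertuples():
        fold = 1.0
        if r.response == "induced":
            fold = (half if condition == "after" else 1.0 / half)
        elif r.response == "repressed":
            fold = (1.0 / half if condition == "after" else half)
        rates[r.chrom][r.start:r.end] = config.enrichment * fold
    # shared scale: stable-mass total (responsive mass is symmetric by design)
    genome = sum(truth.chrom_sizes.values())
    acr = truth.acrs
    stable_mass = ((acr.end - acr.start) * (config.enrichment - 1.0))[
        acr.response == "stable"].sum()
    resp = acr[acr.response != "stable"]
    resp_mass = ((resp.end - resp.start) * (config.enrichment * (half + 1 / half) / 2 - 1)).sum()
    scale = config.library_size / (genome + stable_mass + resp_mass)
    for c in rates:
        rates[c] *= scale
    return rates


def simulate_tis_track(
    genome: SyntheticGenome, truth: GroundTruth, condition: str, replicate: int,
    config: SyntheticConfig | None = None,
) -> tuple[Track, float]:
    """One replicate's per-base TIS counts plus its realized library size.

    Counts are gamma-Poisson: an independent gamma multiplier (shape
    1/dispersion) per 200 bp segment of each planted ACR per sample, so
    segment-level counts are negative binomial with the configured
    dispersion, on top of per-base Poisson background.
    """
    config = config or genome.config
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected {CONDITIONS}")
    rates = _tis_rates(truth, config, condition)
    rng = config.rng("tis", condition, replicate)
    shape = 1.0 / config.nb_dispersion
    seg = 200
    track: Track = {}
    for chrom in sorted(rates):
        lam = rates[chrom].copy()
        acr_here = truth.acrs[truth.acrs.chrom == chrom]
        for r in acr_here.itertuples():
            for s in range(r.start, r.end, seg):
                e = min(s + seg, r.end)
                lam[s:e] *= rng.gamma(shape, 1.0 / shape)
        track[chrom] = rng.poisson(lam).astype(np.float64)
    lib = float(sum(a.sum() for a in track.values()))
    return track, lib


# ---------------------------------------------------------------- mark model

def simulate_mark_tracks(
    genome: SyntheticGenome, truth: GroundTruth, condition: str,
    config: SyntheticConfig | None = None,
    background_rate: float = 0.02, domain_rate: float = 0.6,
) -> dict[str, tuple[Track, list[Interval]]]:
    """Coverage tracks plus peak BED sets for the four histone marks."""
    config = config or genome.config
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    out = {}
    for mark in MARKS:
        rng = config.rng("mark", mark, condition)
        rate = {c: np.full(n, background_rate) for c, n in truth.chrom_sizes.items()}
        domains = truth.mark_domains[(mark, condition)]
        for iv in domains:
            rate[iv.chrom][iv.start : iv.end] = domain_rate
        track = {c: rng.poisson(rate[c]).astype(np.float64) for c in sorted(rate)}
        out[mark] = (track, list(domains))
    return out


# ----------------------------------------------------------- expression model

def simulate_expression(
    genome: SyntheticGenome, truth: GroundTruth,
    config: SyntheticConfig | None = None, depth_factor: float = 1.0,
) -> pd.DataFrame:
    """Gene x sample NB count matrix over both conditions."""
    config = config or genome.config
    rng = config.rng("expression")
    shape = 1.0 / config.nb_dispersion
    genes = truth.genes
    cols = {}
    for cond in CONDITIONS:
        mu = genes[f"mean_{cond}"].to_numpy() * (GENE_LEN / 1000.0) * depth_factor
        for rep in range(1, config.replicates + 1):
            lam = np.where(mu > 0, rng.gamma(shape, np.maximum(mu, 1e-300) / shape), 0.0)
            cols[f"{cond}_{rep}"] = rng.poisson(lam)
    df = pd.DataFrame(cols, index=genes.gene_id.to_numpy())
    df.index.name = "gene_id"
    return df


# ---------------------------------------------------------- auxiliary tracks

def plant_auxiliary_features(
    genome: SyntheticGenome, truth: GroundTruth,
    config: SyntheticConfig | None = None,
) -> dict:
    """SNP/GWAS/TE placements and the PWM set; also stored on the truth."""
    config = config or genome.config
    rng = config.rng("aux")
    sizes = truth.chrom_sizes
    cres = truth.acr_intervals()
    cre_mask = {c: np.zeros(n, dtype=bool) for c, n in sizes.items()}
    for iv in cres:
        cre_mask[iv.chrom][iv.start : iv.end] = True

    snps: list[Interval] = []
    for chrom in sorted(sizes):
        p = np.full(sizes[chrom], config.snp_rate)
        p[cre_mask[chrom]] /= config.snp_depletion
        pos = np.flatnonzero(rng.random(sizes[chrom]) < p)
        snps.extend(Interval(chrom, int(x), int(x) + 1, name="snp") for x in pos)

    resp = truth.responsive_acrs()
    gwas: list[Interval] = []
    n_near = int(round(config.n_gwas * config.frac_gwas_near_cre))
    if len(resp) and n_near:
        pick = rng.integers(0, len(resp), size=n_near)
        offs = rng.integers(-1000, 1001, size=n_near)
        for k, o in zip(pick, offs):
            r = resp.iloc[int(k)]
            pos = int(np.clip((r.start + r.end) // 2 + o, 0, sizes[r.chrom] - 1))
            gwas.append(Interval(r.chrom, pos, pos + 1, name="gwas"))
    chrom_names = sorted(sizes)
    for _ in range(config.n_gwas - len(gwas)):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        pos = int(rng.integers(0, sizes[chrom] - 1))
        gwas.append(Interval(chrom, pos, pos + 1, name="gwas"))

    # TEs: retrotransposons biased onto sub-genome-specific distal elements
    tes: list[Interval] = []
    retro = ["RLG", "RLC", "RIX"]
    dna_te = ["DTT", "DTX", "other"]
    specific = truth.acrs[(truth.acrs.homology == "specific")]
    for r in specific.itertuples():
        if rng.random() < config.frac_te_on_specific:
            fam = retro[int(rng.integers(0, 3))]
            s = max(0, int(r.start) - int(rng.integers(0, 200)))
            tes.append(Interval(r.chrom, s, min(sizes[r.chrom], s + int(rng.integers(400, 1500))), name=fam))
    for chrom in sorted(sizes):
        for _ in range(config.n_te_per_chrom):
            fam = (retro + dna_te)[int(rng.integers(0, 6))]
            s = int(rng.integers(0, sizes[chrom] - 2000))
            tes.append(Interval(chrom, s, s + int(rng.integers(200, 2000)), name=fam))

    truth.snps, truth.gwas, truth.tes = snps, gwas, tes
    truth.pwms = truth.pwms or default_pwms()
    return dict(snps=snps, gwas=gwas, tes=tes, pwms=truth.pwms)


# ------------------------------------------------------------------- bundles

def write_all_tracks(genome: SyntheticGenome, outdir) -> dict[str, str]:
    """Generate and write every assay file for the default experiment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg, truth = genome.config, genome.truth
    genome.write(outdir)
    manifest: dict[str, str] = {}
    for cond in CONDITIONS:
        for rep in range(1, cfg.replicates + 1):
            track, lib = simulate_tis_track(genome, truth, cond, rep, cfg)
            p = outdir / f"tis_{cond}_{rep}.bedgraph"
            write_bedgraph(p, track)
            manifest[f"tis_{cond}_{rep}"] = str(p)
        marks = simulate_mark_tracks(genome, truth, cond, cfg)
        for mark, (track, peaks) in marks.items():
            bp = outdir / f"{mark}_{cond}_peaks.bed"
            write_bed(bp, peaks)
            manifest[f"{mark}_{cond}_peaks"] = str(bp)
    expr = simulate_expression(genome, truth, cfg)
    expr.to_csv(outdir / "expression_counts.tsv", sep="\t")
    aux = plant_auxiliary_features(genome, truth, cfg)
    write_bed(outdir / "snps.bed", aux["snps"])
    write_bed(outdir / "gwas.bed", aux["gwas"])
    write_bed(outdir / "tes.bed", aux["tes"])
    from .motifs import write_pwms
    write_pwms(outdir / "pwms.jaspar", aux["pwms"])
    truth.tf_table.to_csv(outdir / "tf_annotation.tsv", sep="\t", index=False)
    manifest["expression"] = str(outdir / "expression_counts.tsv")
    return manifest
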