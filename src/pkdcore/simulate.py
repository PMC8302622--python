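"""Synthetic bulk RNA-seq data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: three genotypes (a wild-type reference and two knockouts) with four
replicates each, ~25,000 genes with log-normal baseline expression,
negative-binomial counts with a 1/mu + const dispersion trend, per-sample
library-size factors, and a per-cell-line "clonal" log2 expression offset.
The two knockout lines are single-cell-derived clones of the parental
wild-type line, so clonal drift is attributed to the derived clones: each
knockout line carries an independent per-gene N(0, clonal_sd) offset while
the parental reference defines the zero point. When the clonal scale
dominates the genotype-effect scale this reproduces the characteristic PCA
structure in which the leading component captures inter-clone variation and a
later component discriminates both knockouts from wild type.

Planted truth partitions genes into classes: concordant-up / concordant-down
(equal-sign log2 effects of |lfc| >= 1 in BOTH knockouts), discordant
(opposite signs), single-knockout, and null. Exon tables are multinomial
within each gene's per-sample totals, with logit-shifted focal-exon
proportions for planted differential-usage genes. External study lists are
noisy views of the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import CountMatrix, StudyList

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_counts",
    "simulate_exon_counts",
    "simulate_study_lists",
]

CLASSES = (
    "null",
    "concordant_up",
    "concordant_down",
    "discordant",
    "single_ko1",
    "single_ko2",
)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults emulate the study design.

    Three genotypes × ``n_reps`` replicates; 25,000 genes; class fractions
    chosen so that roughly 1% of genes respond concordantly (skewed towards
    down-regulation, as observed in knockout epithelia), with smaller
    discordant and single-knockout fractions.
    """

    n_genes: int = 25_000
    n_reps: int = 4
    genotypes: tuple[str, str, str] = ("WT", "KO1", "KO2")

    frac_concordant_up: float = 0.0015
    frac_concordant_down: float = 0.0085
    frac_discordant: float = 0.005
    frac_single: float = 0.02

    effect_size: float = 2.0           # |log2FC| of planted effects
    effect_min_baseline: float = 50.0  # planted effects land on expressed genes

    baseline_log_mean: float = 4.0     # natural-log scale of the log-normal baseline
    baseline_log_sd: float = 1.5

    dispersion_a0: float = 3.0         # alpha(mu) = a0/mu + a1
    dispersion_a1: float = 0.02

    clonal_sd: float = 0.25            # per-gene log2 drift of each KO clone
    size_factor_range: tuple[float, float] = (0.7, 1.4)

    # exon-level structure
    n_exons_range: tuple[int, int] = (2, 12)
    frac_deu: float = 0.02
    deu_logit_shift: float = 1.5

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ParameterError("n_genes must be positive")
        if self.n_reps < 2:
            raise ParameterError("n_reps must be >= 2")
        fracs = (
            self.frac_concordant_up
            + self.frac_concordant_down
            + self.frac_discordant
            + self.frac_single
        )
        if any(
            f < 0
            for f in (
                self.frac_concordant_up,
                self.frac_concordant_down,
                self.frac_discordant,
                self.frac_single,
            )
        ):
            raise ParameterError("class fractions must be non-negative")
        if fracs > 1.0 + 1e-12:
            raise ParameterError(f"class fractions sum to {fracs:.3f} > 1")
        if len(self.genotypes) != 3:
            raise ParameterError("exactly three genotypes (reference + two KOs) required")
        if self.effect_size < 0 or self.clonal_sd < 0:
            raise ParameterError("effect_size and clonal_sd must be non-negative")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ParameterError("size_factor_range must be positive and ordered")
        lo, hi = self.n_exons_range
        if not (2 <= lo <= hi):
            raise ParameterError("n_exons_range must start at >= 2")
        if not (0 <= self.frac_deu <= 1):
            raise ParameterError("frac_deu must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of one simulated data set.

    ``genes`` holds per-gene baseline mean, dispersion, class label and the
    planted log2 effects in each knockout; ``clonal`` holds the per-genotype
    per-gene clonal offsets (log2); ``size_factors`` the per-sample scaling;
    ``deu`` the planted differentially used exons (filled by
    :func:`simulate_exon_counts`).
    """

    genes: pd.DataFrame
    clonal: pd.DataFrame
    size_factors: pd.Series
    config: SimConfig
    seed: int
    deu: pd.DataFrame | None = None

    @property
    def direction(self) -> pd.Series:
        """Planted direction per gene: sign of the KO1 effect, else KO2, else 0."""
        lfc1 = self.genes["lfc_ko1"]
        lfc2 = self.genes["lfc_ko2"]
        d = np.sign(lfc1)
        d = np.where(d == 0, np.sign(lfc2), d)
        return pd.Series(d.astype(int), index=self.genes.index, name="direction")

    def genes_of_class(self, cls: str) -> list[str]:
        return list(self.genes.index[self.genes["class"] == cls])


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Negative binomial with mean mu, variance mu + alpha*mu^2 (gamma–Poisson)."""
    alpha = np.broadcast_to(alpha, mu.shape)
    lam = np.where(
        alpha > 0,
        rng.gamma(np.where(alpha > 0, 1.0 / np.maximum(alpha, 1e-300), 1.0),
                  np.where(alpha > 0, alpha * mu, 0.0)),
        mu,
    )
    return rng.poisson(lam)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw a gene × sample count matrix with planted effects.

    Counts are negative binomial with mean
    ``baseline * 2**(genotype effect + clonal offset) * size factor`` and
    dispersion ``alpha(baseline) = a0/baseline + a1``. Identical config and
    seed give identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    ref, ko1, ko2 = cfg.genotypes
    genes = [f"G{i:05d}" for i in range(G)]

    # class assignment: a seeded permutation partitions the gene index
    n_up = int(round(cfg.frac_concordant_up * G))
    n_down = int(round(cfg.frac_concordant_down * G))
    n_disc = int(round(cfg.frac_discordant * G))
    n_single = int(round(cfg.frac_single * G))
    perm = rng.permutation(G)
    cls = np.full(G, "null", dtype=object)
    pos = 0
    for name, n in (
        ("concordant_up", n_up),
        ("concordant_down", n_down),
        ("discordant", n_disc),
        ("single_ko1", n_single // 2),
        ("single_ko2", n_single - n_single // 2),
    ):
        cls[perm[pos : pos + n]] = name
        pos += n

    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=G)
    effect_mask = cls != "null"
    # planted effects land on expressed genes: redraw sub-floor baselines
    while True:
        low = effect_mask & (baseline < cfg.effect_min_baseline)
        if not low.any():
            break
        baseline[low] = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=low.sum())

    e = cfg.effect_size
    lfc1 = np.zeros(G)
    lfc2 = np.zeros(G)
    lfc1[cls == "concordant_up"] = e
    lfc2[cls == "concordant_up"] = e
    lfc1[cls == "concordant_down"] = -e
    lfc2[cls == "concordant_down"] = -e
    disc = cls == "discordant"
    disc_sign = rng.choice([-1.0, 1.0], size=int(disc.sum()))
    lfc1[disc] = e * disc_sign
    lfc2[disc] = -e * disc_sign
    s1 = cls == "single_ko1"
    lfc1[s1] = e * rng.choice([-1.0, 1.0], size=int(s1.sum()))
    s2 = cls == "single_ko2"
    lfc2[s2] = e * rng.choice([-1.0, 1.0], size=int(s2.sum()))

    clonal = pd.DataFrame(0.0, index=genes, columns=list(cfg.genotypes))
    for ko in (ko1, ko2):
        clonal[ko] = rng.normal(0.0, cfg.clonal_sd, size=G) if cfg.clonal_sd > 0 else 0.0

    n_samples = 3 * cfg.n_reps
    sample_geno = [g for g in cfg.genotypes for _ in range(cfg.n_reps)]
    samples = [f"{g}_{r + 1}" for g in cfg.genotypes for r in range(cfg.n_reps)]
    lo, hi = cfg.size_factor_range
    sf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))

    effects = pd.DataFrame({ref: np.zeros(G), ko1: lfc1, ko2: lfc2}, index=genes)
    alpha = cfg.dispersion_a0 / baseline + cfg.dispersion_a1

    log2_shift = effects.to_numpy() + clonal.to_numpy()  # genes x genotypes
    geno_idx = np.array([list(cfg.genotypes).index(g) for g in sample_geno])
    mu = baseline[:, None] * np.exp2(log2_shift[:, geno_idx]) * sf[None, :]
    counts = _nb_sample(rng, mu, alpha[:, None])

    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples, dtype=np.int64),
        pd.Series(sample_geno, index=samples, name="genotype"),
        reference=ref,
    )
    truth = SimTruth(
        genes=pd.DataFrame(
            {
                "baseline": baseline,
                "dispersion": alpha,
                "class": cls,
                "lfc_ko1": lfc1,
                "lfc_ko2": lfc2,
            },
            index=pd.Index(genes, name="gene"),
        ),
        clonal=clonal,
        size_factors=pd.Series(sf, index=samples, name="size_factor"),
        config=cfg,
        seed=cfg.seed,
    )
    return cm, truth


def simulate_exon_counts(
    config: SimConfig, truth: SimTruth, cm: CountMatrix
) -> pd.DataFrame:
    """Split each gene's per-sample totals multinomially across its exons.

    Genes receive 2–12 exons with Dirichlet base proportions. For planted
    differential-usage genes the focal exon's proportion is logit-shifted by
    ``deu_logit_shift`` in both knockout genotypes, so that exon counts remain
    an exact partition of the gene total in every sample.

    Returns a long DataFrame with columns ``gene_id``, ``exon_id`` and one
    column per sample; updates ``truth.deu`` in place.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    genes = cm.genes
    G = len(genes)
    lo, hi = cfg.n_exons_range
    n_exons = rng.integers(lo, hi + 1, size=G)

    n_deu = int(round(cfg.frac_deu * G))
    deu_genes = set(rng.choice(G, size=n_deu, replace=False).tolist())
    ref = cm.reference
    ko_genos = [g for g in cm.genotypes if g != ref]
    geno_of = [cm.genotype[s] for s in cm.samples]

    counts = cm.counts.to_numpy()
    deu_rows = []
    out_rows = []
    for gi, gene in enumerate(genes):
        K = int(n_exons[gi])
        props = rng.dirichlet(np.full(K, 5.0))
        focal = -1
        shifted = props
        if gi in deu_genes:
            focal = int(rng.integers(0, K))
            logit = np.log(props[focal] / (1.0 - props[focal])) + cfg.deu_logit_shift
            if not np.isfinite(logit):
                raise ParameterError(
                    f"gene {gene}: logit shift produces a degenerate exon proportion"
                )
            p_new = 1.0 / (1.0 + np.exp(-logit))
            if not (0.0 < p_new < 1.0):
                raise ParameterError(
                    f"gene {gene}: shifted proportion {p_new} outside (0, 1)"
                )
            shifted = props * (1.0 - p_new) / (1.0 - props[focal])
            shifted[focal] = p_new
            deu_rows.append((gene, f"E{focal + 1:02d}", cfg.deu_logit_shift, props[focal]))
        gene_out = np.empty((K, len(geno_of)), dtype=np.int64)
        for si, geno in enumerate(geno_of):
            p = shifted if (gi in deu_genes and geno in ko_genos) else props
            gene_out[:, si] = rng.multinomial(counts[gi, si], p)
        for k in range(K):
            out_rows.append((gene, f"E{k + 1:02d}", *gene_out[k]))

    exon_df = pd.DataFrame(out_rows, columns=["gene_id", "exon_id", *cm.samples])
    truth.deu = pd.DataFrame(
        deu_rows, columns=["gene_id", "exon_id", "logit_shift", "base_proportion"]
    )
    return exon_df


def simulate_study_lists(
    truth: SimTruth,
    n_studies: int,
    sensitivity: float,
    false_hit_rate: float,
    direction_flip_rate: float,
    seed: int,
    species: str = "mouse",
) -> list[StudyList]:
    """Generate noisy external study lists from the planted truth.

    Each true-effect gene enters each study independently with probability
    ``sensitivity`` (with its planted direction, flipped with probability
    ``direction_flip_rate``); each null gene enters with probability
    ``false_hit_rate`` and a random direction.
    """
    if n_studies < 1:
        raise ParameterError("n_studies must be >= 1")
    for name, r in (
        ("sensitivity", sensitivity),
        ("false_hit_rate", false_hit_rate),
        ("direction_flip_rate", direction_flip_rate),
    ):
        if not (0.0 <= r <= 1.0):
            raise ParameterError(f"{name} must be in [0, 1], got {r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    direction = truth.direction
    genes = np.array(direction.index)
    true_mask = direction.to_numpy() != 0
    out = []
    for i in range(n_studies):
        entries: dict[str, int] = {}
        include_true = rng.random(true_mask.sum()) < sensitivity
        flip = rng.random(true_mask.sum()) < direction_flip_rate
        true_dirs = direction.to_numpy()[true_mask]
        for g, take, fl, d in zip(genes[true_mask], include_true, flip, true_dirs):
            if take:
                entries[str(g).upper()] = int(-d if fl else d)
        null_genes = genes[~true_mask]
        include_null = rng.random(null_genes.size) < false_hit_rate
        null_dirs = rng.choice([-1, 1], size=null_genes.size)
        for g, take, d in zip(null_genes, include_null, null_dirs):
            if take:
                entries[str(g).upper()] = int(d)
        out.append(StudyList(f"study{i + 1:02d}", species, entries))
    return out
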