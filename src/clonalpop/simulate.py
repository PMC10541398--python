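"""Synthetic SNP cohorts with the structure the downstream analyses assume.

The generative model, top to bottom:

1. *Populations*: for each of ``K`` ancestral populations, per-site allele
   frequencies follow a Balding–Nichols construction — ancestral frequency
   ``p`` drawn uniformly on a configured range, population frequency drawn
   from a Beta distribution with mean ``p`` and variance ``F_k * p * (1-p)``
   where ``F_k`` is the population's drift (Fst-like) parameter.
2. *Individuals*: the two allele copies at each site are independent
   Bernoulli draws with success probability ``sum_k q_k * f_kj`` for the
   individual's ancestry vector ``q``.  Outbred group members are drawn
   fresh from a single population; clonal group members are somatic copies
   of one founder genotype; admixed members share a configured ``q``.
3. *Noise*: somatic loss of heterozygosity within clones (het -> random
   homozygote at rate ``somatic_mu``); genotyping allele dropout (het ->
   random homozygote at rate ``dropout_d``) and miscall error (hom -> het
   at rate ``error_e``) applied independently per sample; finally each call
   set missing with probability ``missing_m`` (missing completely at
   random).

Technical replicates — independent noisy re-measurements of one true
genotype — can be requested by sample ID; they calibrate the clonality
threshold the same way replicate libraries do in a real RAD-seq study.

Truth tables (true ancestry, clone membership, group label, population
frequencies) accompany every cohort for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotype import MISSING, GenotypeMatrix, SampleMeta, SiteMeta

_MODES = ("outbred", "clonal", "admixed")
_DISTRICTS = (
    "Tohoku", "Kanto", "Chubu", "Kinki", "Chugoku", "Shikoku", "Kyushu", "Okinawa",
)


@dataclass(frozen=True)
class GroupSpec:
    """One sample group: label, size, and how its genotypes arise.

    ``population`` (0-based index) is required for ``outbred`` and
    ``clonal`` modes; ``q`` (length-K ancestry vector summing to 1) is
    required for ``admixed``.
    """

    label: str
    size: int
    mode: str
    population: int | None = None
    q: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.size < 1:
            raise ValueError("group size must be >= 1")
        if self.mode in ("outbred", "clonal") and self.population is None:
            raise ValueError(f"group {self.label!r}: {self.mode} mode needs a population")
        if self.mode == "admixed":
            if self.q is None:
                raise ValueError(f"group {self.label!r}: admixed mode needs a q vector")
            if abs(sum(self.q) - 1.0) > 1e-8:
                raise ValueError(f"group {self.label!r}: q must sum to 1")


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of one synthetic cohort."""

    n_sites: int
    K: int
    drift: tuple[float, ...]
    group_specs: tuple[GroupSpec, ...]
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    dropout_d: float = 0.0
    error_e: float = 0.0
    missing_m: float = 0.0
    somatic_mu: float = 0.0
    replicate_sources: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.drift) != self.K:
            raise ValueError("need one drift value per population")
        for f in self.drift:
            if not 0.0 <= f <= 1.0:
                raise ValueError("drift values must lie in [0, 1]")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("ancestral_freq_range must lie within (0, 1)")
        for p in (self.dropout_d, self.error_e, self.missing_m, self.somatic_mu):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for g in self.group_specs:
            if g.mode in ("outbred", "clonal") and not 0 <= g.population < self.K:
                raise ValueError(
                    f"group {g.label!r} cites population {g.population}, "
                    f"but K={self.K}"
                )
            if g.mode == "admixed" and len(g.q) != self.K:
                raise ValueError(f"group {g.label!r}: q must have length K={self.K}")


@dataclass
class TruthTables:
    """Ground truth for one simulated cohort."""

    true_Q: pd.DataFrame          # samples x K, rows sum to 1
    true_clone_id: pd.Series      # clone lineage label or "" per sample
    true_group_label: pd.Series   # group label per sample
    population_freqs: np.ndarray  # K x n_sites

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.true_Q.to_csv(directory / "true_Q.csv")
        pd.DataFrame(
            {"clone_id": self.true_clone_id, "group": self.true_group_label}
        ).to_csv(directory / "true_labels.csv")
        pd.DataFrame(self.population_freqs).to_csv(
            directory / "population_freqs.csv", index=False
        )


# -- generative building blocks -------------------------------------------

def draw_population_frequencies(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw the K x n_sites population allele-frequency matrix.

    Balding–Nichols: Beta(p(1-F)/F, (1-p)(1-F)/F) has mean p and variance
    F*p*(1-p).  F=0 degenerates to the ancestral frequency itself, F=1 to a
    fixed 0/1 draw with probability p.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.ancestral_freq_range
    p = rng.uniform(lo, hi, size=cfg.n_sites)
    freqs = np.empty((cfg.K, cfg.n_sites))
    for k, F in enumerate(cfg.drift):
        if F == 0.0:
            freqs[k] = p
        elif F == 1.0:
            freqs[k] = (rng.random(cfg.n_sites) < p).astype(float)
        else:
            a = p * (1.0 - F) / F
            b = (1.0 - p) * (1.0 - F) / F
            freqs[k] = rng.beta(a, b)
    return np.clip(freqs, 1e-9, 1.0 - 1e-9)


def simulate_individual(
    q: np.ndarray, freqs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one diploid dosage vector for ancestry ``q`` (sums to 1)."""
    q = np.asarray(q, dtype=float)
    if abs(q.sum() - 1.0) > 1e-8:
        raise ValueError("ancestry vector q must sum to 1")
    pi = q @ freqs
    return rng.binomial(2, pi).astype(np.int8)


def clonal_replicate(
    founder: np.ndarray, somatic_mu: float, rng: np.random.Generator
) -> np.ndarray:
    """Copy a founder genotype with somatic loss of heterozygosity.

    Each het site independently becomes a random homozygote with
    probability ``somatic_mu``; homozygous sites are untouched.
    """
    g = founder.copy()
    het = g == 1
    loh = het & (rng.random(g.shape) < somatic_mu)
    g[loh] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(loh.sum()))
    return g


def apply_genotyping_noise(
    g: np.ndarray, dropout_d: float, error_e: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply allele dropout and miscall error to a true dosage vector.

    True hets become hom-ref or hom-alt (equal probability) with
    probability ``dropout_d``; true homs become het with probability
    ``error_e``.  Dropout direction is the independent equal-probability
    choice the clonality closed form :func:`clonalpop.clonality.
    expected_clonal_conservation` assumes.
    """
    out = g.copy()
    het = g == 1
    hom = (g == 0) | (g == 2)
    drop = het & (rng.random(g.shape) < dropout_d)
    out[drop] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(drop.sum()))
    err = hom & (rng.random(g.shape) < error_e)
    out[err] = 1
    return out


# -- cohort assembly -------------------------------------------------------

def simulate_cohort(cfg: SimulationConfig) -> tuple[GenotypeMatrix, TruthTables]:
    """Assemble a full cohort with truth tables, deterministically per seed.

    Stage order per sample: true genotype (population draw / clonal copy
    with somatic LOH / admixed draw), then genotyping noise, then MCAR
    missingness.  Technical replicates re-apply noise and missingness to
    the source sample's *true* genotype.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_freq, rng_geno, rng_noise, rng_missing, rng_meta = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    freqs = draw_population_frequencies(cfg, rng_freq)
    base = "ACGT"
    ref_idx = rng_meta.integers(0, 4, size=cfg.n_sites)
    alt_shift = rng_meta.integers(1, 4, size=cfg.n_sites)
    sites = [
        SiteMeta(
            locus_id=f"locus_{j:06d}",
            position=1,
            ref_allele=base[ref_idx[j]],
            alt_allele=base[(ref_idx[j] + alt_shift[j]) % 4],
        )
        for j in range(cfg.n_sites)
    ]

    sample_ids: list[str] = []
    regions: list[str] = []
    replicate_of: list[str | None] = []
    true_genotypes: list[np.ndarray] = []
    true_q_rows: list[np.ndarray] = []
    clone_ids: list[str] = []
    group_labels: list[str] = []

    for spec in cfg.group_specs:
        if spec.mode == "clonal":
            onehot = np.zeros(cfg.K)
            onehot[spec.population] = 1.0
            founder = simulate_individual(onehot, freqs, rng_geno)
        for i in range(spec.size):
            sid = f"{spec.label}_{i + 1:02d}"
            if spec.mode == "outbred":
                onehot = np.zeros(cfg.K)
                onehot[spec.population] = 1.0
                g = simulate_individual(onehot, freqs, rng_geno)
                q_row, clone = onehot, ""
            elif spec.mode == "clonal":
                onehot = np.zeros(cfg.K)
                onehot[spec.population] = 1.0
                g = clonal_replicate(founder, cfg.somatic_mu, rng_geno)
                q_row, clone = onehot, f"clone_{spec.label}"
            else:
                q_row = np.asarray(spec.q, dtype=float)
                g = simulate_individual(q_row, freqs, rng_geno)
                clone = ""
            sample_ids.append(sid)
            regions.append(_DISTRICTS[rng_meta.integers(0, len(_DISTRICTS))])
            replicate_of.append(None)
            true_genotypes.append(g)
            true_q_rows.append(q_row)
            clone_ids.append(clone)
            group_labels.append(spec.label)

    for src in cfg.replicate_sources:
        if src not in sample_ids:
            raise ValueError(f"replicate source {src!r} is not a generated sample")
        i = sample_ids.index(src)
        sample_ids.append(f"{src}_rep")
        regions.append(regions[i])
        replicate_of.append(src)
        true_genotypes.append(true_genotypes[i].copy())
        true_q_rows.append(true_q_rows[i])
        clone_ids.append(clone_ids[i] or f"plant_{src}")
        group_labels.append(group_labels[i])
        if not clone_ids[i]:
            clone_ids[i] = f"plant_{src}"

    calls = np.empty((len(sample_ids), cfg.n_sites), dtype=np.int8)
    for i, g in enumerate(true_genotypes):
        calls[i] = apply_genotyping_noise(g, cfg.dropout_d, cfg.error_e, rng_noise)
    if cfg.missing_m > 0:
        calls[rng_missing.random(calls.shape) < cfg.missing_m] = MISSING

    samples = [
        SampleMeta(sid, region_label=reg, replicate_of=rep)
        for sid, reg, rep in zip(sample_ids, regions, replicate_of)
    ]
    matrix = GenotypeMatrix(samples, sites, calls)
    truth = TruthTables(
        true_Q=pd.DataFrame(np.vstack(true_q_rows), index=sample_ids),
        true_clone_id=pd.Series(clone_ids, index=sample_ids, name="clone_id"),
        true_group_label=pd.Series(group_labels, index=sample_ids, name="group"),
        population_freqs=freqs,
    )
    return matrix, truth


# -- presets and config files ---------------------------------------------

def wild_garlic_preset(
    seed: int = 0, n_sites: int = 10000, missing_m: float = 0.10
) -> SimulationConfig:
    """A cohort shaped like a wild Japanese garlic survey.

    Three ancestral populations; two clonal bulb-propagated groups (A, B)
    each descending from a single founder plant; a sexually reproducing
    group C split into a pure subgroup C1 and admixed subgroups C2 (gene
    flow from A only), C3 (from B only, more intense) and C4 (from both);
    three technical replicate pairs.  Dropout d = 0.35 puts expected clone
    conservation at 45%, inside the 43–49% band technical replicates show
    in de novo RAD-seq genotyping.  The default 10000 raw sites (~9400
    after the standard filters) are the scale of a de novo ddRAD SNP
    panel; admixed ancestry fractions (0.2–0.35) give the clearly visible
    gene-flow bars such surveys detect, with flow from B into C stronger
    than from A.
    """
    groups = (
        GroupSpec("A", 6, "clonal", population=0),
        GroupSpec("B", 9, "clonal", population=1),
        GroupSpec("C1", 10, "outbred", population=2),
        GroupSpec("C2", 4, "admixed", q=(0.30, 0.0, 0.70)),
        GroupSpec("C3", 9, "admixed", q=(0.0, 0.35, 0.65)),
        GroupSpec("C4", 11, "admixed", q=(0.20, 0.30, 0.50)),
    )
    return SimulationConfig(
        n_sites=n_sites,
        K=3,
        drift=(0.25, 0.25, 0.10),
        group_specs=groups,
        ancestral_freq_range=(0.1, 0.9),
        dropout_d=0.35,
        error_e=0.005,
        missing_m=missing_m,
        somatic_mu=0.01,
        replicate_sources=("B_01", "B_02", "C4_01"),
        seed=seed,
    )


PRESETS = {"wild-garlic": wild_garlic_preset}


def config_to_yaml(cfg: SimulationConfig, path: str | Path) -> None:
    data = {
        "n_sites": cfg.n_sites,
        "K": cfg.K,
        "drift": list(cfg.drift),
        "ancestral_freq_range": list(cfg.ancestral_freq_range),
        "dropout_d": cfg.dropout_d,
        "error_e": cfg.error_e,
        "missing_m": cfg.missing_m,
        "somatic_mu": cfg.somatic_mu,
        "replicate_sources": list(cfg.replicate_sources),
        "seed": cfg.seed,
        "groups": [
            {
                "label": g.label,
                "size": g.size,
                "mode": g.mode,
                **({"population": g.population} if g.population is not None else {}),
                **({"q": list(g.q)} if g.q is not None else {}),
            }
            for g in cfg.group_specs
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def config_from_yaml(path: str | Path) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text())
    groups = tuple(
        GroupSpec(
            label=g["label"],
            size=g["size"],
            mode=g["mode"],
            population=g.get("population"),
            q=tuple(g["q"]) if "q" in g else None,
        )
        for g in data["groups"]
    )
    return SimulationConfig(
        n_sites=data["n_sites"],
        K=data["K"],
        drift=tuple(data["drift"]),
        group_specs=groups,
        ancestral_freq_range=tuple(data.get("ancestral_freq_range", (0.1, 0.9))),
        dropout_d=data.get("dropout_d", 0.0),
        error_e=data.get("error_e", 0.0),
        missing_m=data.get("missing_m", 0.0),
        somatic_mu=data.get("somatic_mu", 0.0),
        replicate_sources=tuple(data.get("replicate_sources", ())),
        seed=data.get("seed", 0),
    )
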