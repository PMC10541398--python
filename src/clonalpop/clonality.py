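"""Clonal lineage detection via conservation of heterozygous-site positions.

Two somatic copies of one plant share the positions of their heterozygous
sites, up to genotyping noise; two sexually produced relatives do not.  For
a sample pair, restricted to sites called in *both* samples:

* a site is **pairwise-variable** when the pair's four alleles are not all
  identical (i.e. the two calls are not the same homozygote);
* a site is a **conserved heterozygous site** when both calls are het;
* the conservation percentage is ``100 * conserved / variable``.

De novo RAD-seq genotyping drops alleles of true heterozygotes, so even
technical replicates of one DNA sample sit well below 100%.  Under
independent allele dropout at rate ``d`` on each copy, a clone pair's
expected conservation is ``100 * (1-d)^2 / (1 - d^2/2)`` — about 45% at
d = 0.35, matching the 40–50% band replicate libraries show in practice.
The decision threshold is therefore calibrated from technical replicates
when available and defaults to 40%.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def round_percent(value: float, decimals: int = 1, mode: str = "half-up") -> float:
    """Round a percentage for tabular display (raw ratios stay untouched).

    ``half-up`` is the default; ``truncate`` chops toward zero, which some
    legacy tabulations use.
    """
    if mode == "half-up":
        q = Decimal(1).scaleb(-decimals)
        return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
    if mode == "truncate":
        factor = 10 ** decimals
        return int(value * factor) / factor
    raise ValueError(f"unknown rounding mode {mode!r}")


@dataclass(frozen=True)
class PairConservation:
    """Conservation of heterozygous sites for one sample pair."""

    sample_a: str
    sample_b: str
    n_variable: int
    n_conserved_het: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_conserved_het <= max(self.n_variable, 0):
            raise ValueError("need 0 <= n_conserved_het <= n_variable")

    @property
    def inconclusive(self) -> bool:
        return self.n_variable == 0

    @property
    def percent(self) -> float:
        """Raw conservation percentage; NaN when no variable sites exist."""
        if self.n_variable == 0:
            return float("nan")
        return 100.0 * self.n_conserved_het / self.n_variable

    @property
    def percent_display(self) -> float:
        return round_percent(self.percent)


@dataclass(frozen=True)
class ClonalityConfig:
    """Decision threshold for calling a pair clonal.

    ``threshold_percent`` defaults to 40; pairs within ``borderline_band``
    points below the threshold are annotated "borderline" rather than
    silently rejected, because somatic loss of heterozygosity during long
    clonal propagation legitimately depresses conservation a few points.
    Pairs with fewer than ``min_variable_sites`` shared variable sites are
    inconclusive.
    """

    threshold_percent: float = 40.0
    borderline_band: float = 4.0
    min_variable_sites: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold_percent <= 100.0:
            raise ValueError("threshold_percent must lie in [0, 100]")
        if self.borderline_band < 0:
            raise ValueError("borderline_band must be >= 0")


def conservation_percent(n_variable: int, n_conserved_het: int) -> float:
    """100 * conserved / variable, the tabular one-decimal statistic (half-up)."""
    if n_variable < 1:
        raise ValueError("n_variable must be >= 1")
    if not 0 <= n_conserved_het <= n_variable:
        raise ValueError("need 0 <= n_conserved_het <= n_variable")
    return round_percent(100.0 * n_conserved_het / n_variable)


def count_pairwise_conservation(
    matrix: GenotypeMatrix, sample_a: str, sample_b: str
) -> PairConservation:
    """Count pairwise-variable and conserved-het sites for one pair.

    Only sites non-missing in both samples enter the counts (the
    two-sample, complete-presence contract); sites where both calls are
    the same homozygote are monomorphic for the pair and excluded from the
    denominator.
    """
    if sample_a == sample_b:
        raise ValueError("sample_a and sample_b must differ")
    ga = matrix.sample_calls(sample_a)
    gb = matrix.sample_calls(sample_b)
    shared = (ga != MISSING) & (gb != MISSING)
    a, b = ga[shared], gb[shared]
    both_het = (a == 1) & (b == 1)
    same_hom = (a == b) & (a != 1)
    n_variable = int((~same_hom).sum())
    n_conserved = int(both_het.sum())
    return PairConservation(sample_a, sample_b, n_variable, n_conserved)


def pairwise_conservation_table(
    matrix: GenotypeMatrix,
    sample_ids: list[str] | None = None,
    cfg: ClonalityConfig | None = None,
) -> pd.DataFrame:
    """All-pairs conservation table with a verdict column.

    Columns: sample_a, sample_b, n_variable, n_conserved_het, percent
    (one-decimal display rounding), verdict in {clonal, borderline,
    non-clonal, inconclusive}.
    """
    cfg = cfg or ClonalityConfig()
    ids = sample_ids or matrix.sample_ids
    rows = []
    for a, b in itertools.combinations(ids, 2):
        pc = count_pairwise_conservation(matrix, a, b)
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "n_variable": pc.n_variable,
                "n_conserved_het": pc.n_conserved_het,
                "percent": pc.percent_display if not pc.inconclusive else np.nan,
                "verdict": _verdict(pc, cfg),
            }
        )
    return pd.DataFrame(rows)


def _verdict(pc: PairConservation, cfg: ClonalityConfig) -> str:
    if pc.inconclusive or pc.n_variable < cfg.min_variable_sites:
        return "inconclusive"
    if pc.percent >= cfg.threshold_percent:
        return "clonal"
    if pc.percent >= cfg.threshold_percent - cfg.borderline_band:
        return "borderline"
    return "non-clonal"


def expected_clonal_conservation(dropout_d: float) -> float:
    """Expected conservation % between clone copies under dropout rate ``d``.

    At a founder-het site each copy independently stays het with
    probability ``1-d`` or becomes either homozygote with probability
    ``d/2`` each.  Both-het has probability ``(1-d)^2``; the site leaves
    the denominator only when both copies become the *same* homozygote,
    probability ``d^2/2``.  Hence 100*(1-d)^2 / (1 - d^2/2).
    """
    if not 0.0 <= dropout_d < 1.0:
        raise ValueError("dropout_d must lie in [0, 1)")
    return 100.0 * (1.0 - dropout_d) ** 2 / (1.0 - dropout_d**2 / 2.0)


def calibrate_threshold(
    replicate_percents: list[float],
    default_threshold: float = 40.0,
    margin: float = 4.0,
) -> ClonalityConfig:
    """Set the clonal threshold from technical-replicate conservation values.

    Threshold = max(default, min(replicates) - margin): replicates bound
    the conservation genotyping noise alone allows, and true clones may sit
    a margin below them due to somatic mutation.  Without replicates the
    default is used with a warning.
    """
    if not replicate_percents:
        logger.warning("no replicate pairs: falling back to default threshold %.1f",
                       default_threshold)
        return ClonalityConfig(threshold_percent=default_threshold)
    lowest = min(replicate_percents)
    threshold = max(default_threshold, lowest - margin)
    logger.info(
        "calibrated clonal threshold %.1f from replicate conservations %s",
        threshold, [round_percent(p) for p in replicate_percents],
    )
    return ClonalityConfig(threshold_percent=threshold)


@dataclass
class ClonalPartition:
    """Result of clonal-group calling."""

    groups: list[set[str]]            # connected components, size >= 2
    singletons: set[str]
    borderline_pairs: list[tuple[str, str, float]]
    inconclusive_pairs: list[tuple[str, str]]

    def clone_id_of(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for i, grp in enumerate(self.groups):
            for sid in sorted(grp):
                out[sid] = f"clone_{i + 1}"
        return out


def call_clonal_groups(
    table: pd.DataFrame, cfg: ClonalityConfig | None = None
) -> ClonalPartition:
    """Partition samples into clonal groups from an all-pairs table.

    Pairs at or above the threshold become graph edges; clonal groups are
    the connected components of size >= 2 (transitive closure: a lineage
    is grouped by cluster membership, not by requiring every pair to
    pass).  Borderline pairs (within the band below threshold) are
    reported for user review but do not create edges; inconclusive pairs
    are listed separately.
    """
    cfg = cfg or ClonalityConfig()
    samples: set[str] = set(table["sample_a"]) | set(table["sample_b"])
    parent = {s: s for s in samples}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    borderline: list[tuple[str, str, float]] = []
    inconclusive: list[tuple[str, str]] = []
    for row in table.itertuples(index=False):
        if row.n_variable == 0 or row.n_variable < cfg.min_variable_sites:
            inconclusive.append((row.sample_a, row.sample_b))
            continue
        pct = 100.0 * row.n_conserved_het / row.n_variable
        if pct >= cfg.threshold_percent:
            parent[find(row.sample_a)] = find(row.sample_b)
        elif pct >= cfg.threshold_percent - cfg.borderline_band:
            borderline.append((row.sample_a, row.sample_b, round_percent(pct)))

    components: dict[str, set[str]] = {}
    for s in samples:
        components.setdefault(find(s), set()).add(s)
    groups = sorted(
        (grp for grp in components.values() if len(grp) >= 2),
        key=lambda g: sorted(g)[0],
    )
    grouped = set().union(*groups) if groups else set()
    return ClonalPartition(
        groups=groups,
        singletons=samples - grouped,
        borderline_pairs=borderline,
        inconclusive_pairs=inconclusive,
    )
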