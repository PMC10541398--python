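"""Group and subgroup classification from K=3 admixture proportions.

The grouping logic mirrors a survey design with two clonally propagated
lineages and one sexual meta-population: the two ancestry clusters whose
members are near-pure *and* coincide with called clonal groups anchor the
labels A and B; the remaining cluster anchors C.  Samples anchored to C are
then split by detected gene flow: ancestry from A and/or B above a
threshold tau assigns C2 (A only), C3 (B only), C4 (both) or C1 (neither).

tau is a reporting choice, not an estimate — it is echoed into every output
so the classification is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds for anchor identification and gene-flow detection.

    ``gene_flow_tau``: minimum ancestry proportion counted as detected gene
    flow.  ``purity_threshold``: minimum dominant-ancestry proportion for a
    sample to count as pure when identifying anchor clusters.
    """

    gene_flow_tau: float = 0.05
    purity_threshold: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.gene_flow_tau < self.purity_threshold <= 1.0:
            raise ValueError("need 0 < tau < purity_threshold <= 1")


@dataclass
class AnchorMap:
    """Mapping from Q columns to the labels A, B, C."""

    column_labels: dict[str, str]       # Q column name -> {A, B, C}
    warnings: list[str] = field(default_factory=list)

    def column_of(self, label: str) -> str:
        for col, lab in self.column_labels.items():
            if lab == label:
                return col
        raise KeyError(label)


def identify_anchor_clusters(
    Q: pd.DataFrame,
    clonal_sample_ids: set[str] | None = None,
    cfg: ClassificationConfig | None = None,
) -> AnchorMap:
    """Label the three ancestry clusters A, B and C.

    A cluster's members are the samples whose dominant ancestry is that
    cluster.  The two clusters whose members are near-pure (dominant q >=
    purity threshold) and sit inside called clonal groups become A and B —
    the smaller cluster is A (a fixed, arbitrary-but-deterministic rule);
    the remaining cluster is C.  With fewer than two pure clonal clusters
    the two purest clusters are used instead, with a warning.
    """
    cfg = cfg or ClassificationConfig()
    if Q.shape[1] != 3:
        raise ValueError("anchor identification expects K=3 ancestry columns")
    clonal_sample_ids = clonal_sample_ids or set()
    cols = list(Q.columns)
    dominant = Q.to_numpy().argmax(axis=1)
    warnings: list[str] = []

    scores = []
    for k, col in enumerate(cols):
        members = Q.index[dominant == k]
        if len(members) == 0:
            scores.append((col, 0, 0.0, 0.0))
            continue
        purity = float((Q.loc[members].to_numpy().max(axis=1)
                        >= cfg.purity_threshold).mean())
        clonal_frac = float(np.mean([s in clonal_sample_ids for s in members]))
        scores.append((col, len(members), purity, clonal_frac))

    pure_clonal = [s for s in scores
                   if s[1] > 0 and s[2] >= 0.5 and s[3] >= 0.5]
    if len(pure_clonal) >= 2:
        # most clonal/pure first; among those, smaller cluster becomes A
        pure_clonal.sort(key=lambda s: (-s[3], -s[2]))
        ab = sorted(pure_clonal[:2], key=lambda s: (s[1], s[0]))
    else:
        msg = (f"only {len(pure_clonal)} pure clonal clusters found; "
               "assigning A/B by purity alone")
        warnings.append(msg)
        logger.warning(msg)
        by_purity = sorted(scores, key=lambda s: (-s[2], s[0]))
        ab = sorted(by_purity[:2], key=lambda s: (s[1], s[0]))
        if all(s[2] == 0.0 for s in scores):
            msg = "no near-pure cluster exists; A/B/C labels are arbitrary"
            warnings.append(msg)
            logger.warning(msg)
    label_map = {ab[0][0]: "A", ab[1][0]: "B"}
    (c_col,) = [c for c in cols if c not in label_map]
    label_map[c_col] = "C"
    return AnchorMap(label_map, warnings)


@dataclass(frozen=True)
class GroupAssignment:
    """Final labels for one sample."""

    sample_id: str
    group: str                      # A, B or C
    subgroup: str                   # C1..C4, or "" outside group C
    q_A: float
    q_B: float
    q_C: float


def classify_subgroups(
    Q: pd.DataFrame,
    anchors: AnchorMap,
    cfg: ClassificationConfig | None = None,
) -> pd.DataFrame:
    """Assign each sample a major group and, within C, a gene-flow subgroup.

    Major group = label of the dominant ancestry cluster.  For C samples:
    q_A >= tau and q_B < tau -> C2; q_B >= tau and q_A < tau -> C3; both ->
    C4; neither -> C1.  The four predicates are mutually exclusive and
    exhaustive, and raising tau can only move samples toward C1.
    """
    cfg = cfg or ClassificationConfig()
    col_A, col_B, col_C = (anchors.column_of(x) for x in "ABC")
    rows = []
    for sid, q in Q.iterrows():
        qa, qb, qc = float(q[col_A]), float(q[col_B]), float(q[col_C])
        group = anchors.column_labels[q.idxmax()]
        subgroup = ""
        if group == "C":
            flow_a, flow_b = qa >= cfg.gene_flow_tau, qb >= cfg.gene_flow_tau
            subgroup = {(False, False): "C1", (True, False): "C2",
                        (False, True): "C3", (True, True): "C4"}[(flow_a, flow_b)]
        rows.append(GroupAssignment(sid, group, subgroup, qa, qb, qc))
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("sample_id")
    df.attrs["gene_flow_tau"] = cfg.gene_flow_tau
    return df


@dataclass
class RegionalReport:
    """Group x region cross-tabulation with a descriptive permutation test."""

    crosstab: pd.DataFrame
    p_value: float | None
    n_permutations: int
    note: str = ""


def regional_structure_report(
    assignment: pd.DataFrame,
    region_labels: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> RegionalReport:
    """Cross-tabulate groups against regions and permutation-test association.

    The statistic is the contingency chi-square; the p-value comes from
    shuffling region labels, so it is valid at any cell-count size.  It is
    descriptive — a large p says the sampled regions show no detectable
    group structure.  Samples without a region label are excluded (and
    counted in the note).
    """
    groups = assignment["group"].astype(str)
    regions = region_labels.reindex(groups.index)
    keep = regions.notna()
    n_excluded = int((~keep).sum())
    groups, regions = groups[keep], regions[keep].astype(str)
    crosstab = pd.crosstab(groups, regions)
    note = f"{n_excluded} samples without region label excluded" if n_excluded else ""

    if crosstab.shape[0] < 2 or crosstab.shape[1] < 2:
        return RegionalReport(crosstab, None, 0,
                              (note + "; " if note else "")
                              + "association test skipped: needs >= 2 groups "
                                "and >= 2 regions")

    def chi2_stat(g: np.ndarray, r: np.ndarray) -> float:
        tab = pd.crosstab(pd.Series(g), pd.Series(r)).to_numpy(dtype=float)
        exp = tab.sum(1, keepdims=True) @ tab.sum(0, keepdims=True) / tab.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(exp > 0, (tab - exp) ** 2 / exp, 0.0)
        return float(terms.sum())

    g = groups.to_numpy()
    r = regions.to_numpy()
    observed = chi2_stat(g, r)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if chi2_stat(g, rng.permutation(r)) >= observed - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return RegionalReport(crosstab, p, n_permutations, note)
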