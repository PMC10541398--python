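"""Per-population diversity statistics and pairwise differentiation.

Site-level quantities, each computed from non-missing diploid calls:

* expected heterozygosity ``He = 1 - p^2 - q^2`` (allele-frequency based);
* nucleotide diversity ``pi = 2 * n_ref * n_alt / (n * (n - 1))`` with
  ``n`` the number of sampled alleles — the unbiased mean pairwise
  difference;
* inbreeding coefficient ``Fis = 1 - Ho / He`` with ``Ho`` the observed
  het fraction (negative values indicate heterozygote excess, the
  signature of clonal propagation of a heterozygous founder);
* pairwise ``Fst`` as the Weir–Cockerham (1984) theta, estimated per site
  from the a/b/c variance components and combined across sites as a ratio
  of sums.  Negative per-site components are retained in the sums.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


def _clean(calls: np.ndarray) -> np.ndarray:
    calls = np.asarray(calls)
    return calls[calls != MISSING]


def site_he(calls: np.ndarray) -> float:
    """Expected heterozygosity 1 - p^2 - q^2 at one site."""
    g = _clean(calls)
    if g.size == 0:
        raise StatsError("no non-missing calls at site")
    p = g.sum() / (2.0 * g.size)
    return float(1.0 - p**2 - (1.0 - p) ** 2)


def site_pi(calls: np.ndarray) -> float:
    """Unbiased nucleotide diversity at one site (mean pairwise difference)."""
    g = _clean(calls)
    n = 2 * g.size
    if n < 2:
        raise StatsError("need >= 2 alleles at site")
    n_alt = int(g.sum())
    n_ref = n - n_alt
    return float(2.0 * n_ref * n_alt / (n * (n - 1)))


def site_fis(calls: np.ndarray) -> float:
    """Inbreeding coefficient 1 - Ho/He at one polymorphic site."""
    g = _clean(calls)
    he = site_he(g)
    if he == 0.0:
        raise StatsError("site is monomorphic in this population (He = 0)")
    ho = float((g == 1).sum() / g.size)
    return float(1.0 - ho / he)


# -- Weir-Cockerham theta --------------------------------------------------

def _wc_site_arrays(
    matrix: GenotypeMatrix, pops: list[list[int]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-population n_i (individuals), p_i (alt freq), h_i (het fraction),
    each shaped (r, n_sites); entries NaN where a population has no data."""
    r = len(pops)
    S = matrix.n_sites
    n = np.zeros((r, S))
    p = np.full((r, S), np.nan)
    h = np.full((r, S), np.nan)
    for k, idx in enumerate(pops):
        sub = matrix.calls[idx]
        valid = sub != MISSING
        cnt = valid.sum(axis=0)
        n[k] = cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(valid, sub, 0).sum(axis=0) / (2.0 * cnt)
            h[k] = np.where(valid & (sub == 1), 1, 0).sum(axis=0) / cnt
    return n, p, h


def _wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) a, b, c variance components per site.

    Inputs are (r, S) arrays of per-population sample sizes (diploid
    individuals), allele frequencies, and observed het fractions.
    """
    r = n.shape[0]
    nbar = n.mean(axis=0)
    nsum = r * nbar
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n * p).sum(axis=0) / nsum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / nsum
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    return a, b, c


def pairwise_fst(
    matrix: GenotypeMatrix,
    assignment: dict[str, str] | pd.Series,
    pop1: str,
    pop2: str,
) -> float:
    """Weir-Cockerham theta between two populations, ratio-of-sums across sites."""
    assignment = dict(assignment)
    idx1 = [matrix.sample_index(s) for s, p in assignment.items() if p == pop1]
    idx2 = [matrix.sample_index(s) for s, p in assignment.items() if p == pop2]
    if len(idx1) < 2 or len(idx2) < 2:
        raise StatsError("both populations need >= 2 individuals")
    n, p, h = _wc_site_arrays(matrix, [idx1, idx2])
    usable = (n >= 1).all(axis=0) & (n.mean(axis=0) > 1)
    if not usable.any():
        raise StatsError("no sites with data in both populations")
    a, b, c = _wc_components(n[:, usable], p[:, usable], h[:, usable])
    denom = np.nansum(a + b + c)
    if denom == 0:
        raise StatsError("no shared polymorphic sites between the populations")
    return float(np.nansum(a) / denom)


@dataclass(frozen=True)
class PopulationStats:
    """Per-population summary: means of He, pi and Fis over included sites."""

    population: str
    n_individuals: int
    n_sites_included: int
    mean_He: float
    mean_pi: float
    mean_Fis: float


def population_stats(
    matrix: GenotypeMatrix,
    sample_ids: list[str],
    label: str,
    min_presence: float = 0.7,
) -> PopulationStats:
    """Diversity statistics for one population.

    Sites must be genotyped in at least ``min_presence`` of the
    population's members.  He and pi average over all included sites
    (monomorphic-within-population sites contribute 0); Fis averages over
    the sites polymorphic within the population, where it is defined.
    """
    idx = [matrix.sample_index(s) for s in sample_ids]
    sub = matrix.calls[idx]
    valid = sub != MISSING
    presence = valid.sum(axis=0) / len(idx)
    keep = presence >= min_presence
    n_skip = int((~keep).sum())
    if n_skip:
        logger.info("population %s: %d sites below presence %.2f skipped",
                    label, n_skip, min_presence)
    if not keep.any():
        raise StatsError(f"population {label!r}: no sites pass the presence filter")

    he_vals, pi_vals, fis_vals = [], [], []
    for j in np.nonzero(keep)[0]:
        col = sub[:, j]
        g = col[col != MISSING]
        if 2 * g.size < 2:
            continue
        he = site_he(g)
        he_vals.append(he)
        pi_vals.append(site_pi(g))
        if he > 0:
            fis_vals.append(site_fis(g))
    return PopulationStats(
        population=label,
        n_individuals=len(idx),
        n_sites_included=len(he_vals),
        mean_He=float(np.mean(he_vals)),
        mean_pi=float(np.mean(pi_vals)),
        mean_Fis=float(np.mean(fis_vals)) if fis_vals else float("nan"),
    )


def population_summary(
    matrix: GenotypeMatrix,
    assignment: dict[str, str] | pd.Series,
    min_presence: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population diversity table and pairwise Fst matrix.

    Populations with fewer than two members are excluded with a warning.
    Returns (stats table indexed by population, symmetric Fst matrix).
    """
    assignment = dict(assignment)
    members: dict[str, list[str]] = {}
    for s, p in assignment.items():
        members.setdefault(str(p), []).append(s)
    labels = sorted(members)
    usable = []
    for lab in labels:
        if len(members[lab]) < 2:
            logger.warning("population %s has < 2 members; excluded", lab)
        else:
            usable.append(lab)

    rows = []
    for lab in usable:
        st = population_stats(matrix, members[lab], lab, min_presence)
        rows.append(
            {
                "population": st.population,
                "n_individuals": st.n_individuals,
                "n_sites": st.n_sites_included,
                "mean_He": st.mean_He,
                "mean_pi": st.mean_pi,
                "mean_Fis": st.mean_Fis,
            }
        )
    stats = pd.DataFrame(rows).set_index("population") if rows else pd.DataFrame()

    fst = pd.DataFrame(0.0, index=usable, columns=usable)
    for p1, p2 in itertools.combinations(usable, 2):
        theta = pairwise_fst(matrix, assignment, p1, p2)
        fst.loc[p1, p2] = theta
        fst.loc[p2, p1] = theta
    if len(usable) < 2:
        fst = pd.DataFrame()
    return stats, fst
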