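"""Epigenetic hallmark derivation and the supporting association statistics.

Differentially methylated region (DMR) sets called per disease subset are
combined by set algebra into three hallmark signatures:

* DTE (dynamic tumor evolution): DMRs unique to either the pre- or the
  post-treatment subset,
* PP (PARPi predictive): DMRs unique to resistant or sensitive patients
  before treatment,
* PR (PARPi response): the same contrast after treatment/progression,

each restricted to DMRs also found in tumor tissue, so that blood-only
(e.g. immune-cell) methylation changes are excluded.  The module also
provides the Cox proportional-hazards screen linking per-region methylation
to time to treatment failure (TTF), uncorrected chi-square and exact Fisher
tests for 2x2 group tables, hypergeometric gene-set enrichment with
enrichment factors, kappa-similarity term clustering, tumor-driver/HRD gene
list annotation, and Spearman average-linkage sample clustering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

HALLMARK_NAMES = ("DTE", "PP", "PR")

#: subset keys required to derive the hallmarks
REQUIRED_SUBSETS = ("pre", "post", "preR", "preS", "postR", "postS", "tissue")


@dataclass
class DMRSet:
    """A named set of DMR region ids with their effect sizes and q-values."""

    name: str
    contrast: str
    log2fc: dict[str, float]
    q: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = self.region_ids - set(self.log2fc)
        if missing:
            raise ValueError(f"DMRSet {self.name}: regions without log2fc: {missing}")

    @property
    def region_ids(self) -> set[str]:
        return set(self.log2fc)

    def __len__(self) -> int:
        return len(self.log2fc)

    @classmethod
    def from_records(cls, name: str, contrast: str, records) -> "DMRSet":
        """Build from an iterable of DMRecord-like objects (region_id, log2fc, q)."""
        return cls(
            name=name,
            contrast=contrast,
            log2fc={r.region_id: r.log2fc for r in records},
            q={r.region_id: r.q for r in records},
        )


@dataclass
class HallmarkSet:
    """A hallmark DMR set with per-region provenance (which subset it was unique to)."""

    name: str
    region_ids: set[str]
    provenance: dict[str, str]
    tissue_restricted: bool = True
    log2fc: dict[str, float] = field(default_factory=dict)

    def side_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for side in self.provenance.values():
            counts[side] = counts.get(side, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.region_ids)


# ---------------------------------------------------------------------------
# set algebra


def unique_and_shared(a: DMRSet, b: DMRSet) -> tuple[set[str], set[str], set[str]]:
    """Partition a ∪ b into (unique to a, unique to b, shared)."""
    ids_a, ids_b = a.region_ids, b.region_ids
    return ids_a - ids_b, ids_b - ids_a, ids_a & ids_b


def tissue_restrict(candidates: set[str], tissue: DMRSet) -> set[str]:
    """Keep only candidate DMRs also called in tumor tissue."""
    kept = candidates & tissue.region_ids
    if candidates and not kept:
        warnings.warn("tissue restriction removed every candidate DMR", stacklevel=2)
    return kept


def define_hallmarks(
    subset_dmrs: Mapping[str, DMRSet],
) -> dict[str, HallmarkSet]:
    """Derive the DTE, PP and PR hallmark sets from per-subset DMR calls.

    ``subset_dmrs`` must provide the keys ``pre, post, preR, preS, postR,
    postS, tissue``.  Each hallmark takes the DMRs unique to either side of
    its defining comparison, restricted to the tissue DMR set; provenance
    records the side each region was unique to.
    """
    for key in REQUIRED_SUBSETS:
        if key not in subset_dmrs:
            raise ValueError(f"missing DMR subset: {key!r}")
    tissue = subset_dmrs["tissue"]
    comparisons = {
        "DTE": ("pre", "post"),
        "PP": ("preR", "preS"),
        "PR": ("postR", "postS"),
    }
    out: dict[str, HallmarkSet] = {}
    for name, (left, right) in comparisons.items():
        a, b = subset_dmrs[left], subset_dmrs[right]
        ua, ub, _ = unique_and_shared(a, b)
        ua, ub = tissue_restrict(ua, tissue), tissue_restrict(ub, tissue)
        provenance = {r: f"{left}-unique" for r in ua}
        provenance.update({r: f"{right}-unique" for r in ub})
        log2fc = {r: a.log2fc[r] for r in ua}
        log2fc.update({r: b.log2fc[r] for r in ub})
        out[name] = HallmarkSet(
            name=name,
            region_ids=ua | ub,
            provenance=provenance,
            tissue_restricted=True,
            log2fc=log2fc,
        )
    return out


def hallmark_overlap(hallmarks: Mapping[str, HallmarkSet]) -> dict[str, int]:
    """Venn-style region counts over the three hallmark sets."""
    sets = {name: h.region_ids for name, h in hallmarks.items()}
    names = sorted(sets)
    out: dict[str, int] = {}
    for name in names:
        others = set().union(*(sets[o] for o in names if o != name))
        out[f"{name}_only"] = len(sets[name] - others)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[f"{a}&{b}"] = len(sets[a] & sets[b])
    out["all"] = len(set.intersection(*sets.values())) if names else 0
    return out


# ---------------------------------------------------------------------------
# Cox proportional hazards (single covariate, Breslow ties)


@dataclass
class CoxFit:
    region_id: str
    log_hr: float
    se: float
    p: float
    n_iter: int

    @property
    def hr(self) -> float:
        return math.exp(self.log_hr)


def cox_ttf(
    values: Sequence[float],
    time: Sequence[float],
    event: Sequence[int] | None = None,
    region_id: str = "region",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxFit:
    """Single-covariate Cox partial-likelihood fit by damped Newton iteration.

    Ties are handled with the Breslow approximation.  All subjects are events
    unless an event indicator is given (time to treatment failure is observed
    for everyone when stopping therapy itself ends the interval).  The Wald
    p-value uses the normal reference for log_hr / se.
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.ones_like(t) if event is None else np.asarray(event, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 subjects")
    if np.ptp(x) == 0:
        raise ValueError("no variation in covariate")
    order = np.argsort(t, kind="stable")
    x, t, d = x[order], t[order], d[order]

    def neg_loglik_grad_hess(beta: float):
        eta = beta * x
        eta -= eta.max()  # overflow guard; partial likelihood is shift-invariant
        w = np.exp(eta)
        # risk set at the i-th smallest time = samples i..n-1 (Breslow)
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((w * x)[::-1])[::-1]
        s2 = np.cumsum((w * x * x)[::-1])[::-1]
        ll = np.sum(d * (eta - np.log(s0)))  # shift cancels term-by-term
        grad = np.sum(d * (x - s1 / s0))
        hess = -np.sum(d * (s2 / s0 - (s1 / s0) ** 2))
        return -ll, -grad, -hess

    beta = 0.0
    nll, grad, hess = neg_loglik_grad_hess(beta)
    for it in range(1, max_iter + 1):
        if abs(grad) < tol:
            break
        step = -grad / max(hess, 1e-12)
        # damping: halve until the objective does not increase
        for _ in range(30):
            cand = beta + step
            nll_new, grad_new, hess_new = neg_loglik_grad_hess(cand)
            if nll_new <= nll + 1e-12:
                break
            step /= 2
        beta, nll, grad, hess = cand, nll_new, grad_new, hess_new
    else:
        raise RuntimeError(f"Cox fit did not converge in {max_iter} iterations")
    se = 1.0 / math.sqrt(max(hess, 1e-300))
    z = beta / se
    p = 2 * stats.norm.sf(abs(z))
    return CoxFit(region_id=region_id, log_hr=beta, se=se, p=float(p), n_iter=it)


def cox_screen(
    matrix: pd.DataFrame,
    time: Mapping[str, float],
    event: Mapping[str, int] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region Cox TTF screen over a regions-by-samples covariate matrix.

    Rows are regions, columns sample ids present in ``time``.  Regions whose
    fit fails (constant covariate, non-convergence) are reported with NaN.
    Returns a DataFrame (region, log_hr, hr, se, p, significant).
    """
    samples = [s for s in matrix.columns if s in time]
    t = [time[s] for s in samples]
    e = None if event is None else [event[s] for s in samples]
    rows = []
    for region, vals in matrix[samples].iterrows():
        try:
            fit = cox_ttf(vals.to_numpy(), t, e, region_id=str(region))
            rows.append(
                {"region": region, "log_hr": fit.log_hr, "hr": fit.hr,
                 "se": fit.se, "p": fit.p}
            )
        except (ValueError, RuntimeError):
            rows.append(
                {"region": region, "log_hr": np.nan, "hr": np.nan,
                 "se": np.nan, "p": np.nan}
            )
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < alpha
    return out


# ---------------------------------------------------------------------------
# 2x2 group tests


def chi2_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table: N(ad-bc)^2 / (r1 r2 c1 c2), df=1.

    No continuity correction by default; ``correction=True`` applies Yates.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    (a, b), (c, d) = tab
    n = tab.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin: chi-square undefined")
    diff = abs(a * d - b * c)
    if correction:
        diff = max(0.0, diff - n / 2)
    chi2 = n * diff**2 / (r1 * r2 * c1 * c2)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric table probabilities
    not exceeding the observed table's probability (with a small relative
    tolerance against floating-point ties)."""
    tab = np.asarray(table, dtype=int)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a non-negative integer 2x2 table")
    (a, b), (c, d) = tab
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0:
        return 1.0
    rv = stats.hypergeom(n, c1, r1)  # a ~ Hypergeom(N=n, K=c1, n=r1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-7)].sum()))


# ---------------------------------------------------------------------------
# gene-set enrichment and kappa clustering


def enrich(
    query: set[str],
    terms: Mapping[str, set[str]],
    background: set[str],
    p_max: float = 0.01,
    min_overlap: int = 3,
    min_factor: float = 1.5,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` genes in each term.

    For a term of size K in a background of N genes and a query of n genes
    with overlap k, p = P[X >= k], X ~ Hypergeom(N, K, n), and the enrichment
    factor is (k/n)/(K/N).  The default filter keeps terms with p < 0.01,
    k >= 3 and factor > 1.5; a BH-adjusted column is reported alongside.
    """
    query = query & background
    if not query:
        raise ValueError("query is empty after restriction to the background")
    if not terms:
        raise ValueError("no terms supplied")
    N, n = len(background), len(query)
    rows = []
    for term_id, genes in terms.items():
        genes_bg = genes & background
        K = len(genes_bg)
        overlap = query & genes_bg
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        factor = (k / n) / (K / N) if K > 0 else 0.0
        rows.append(
            {"term": term_id, "K": K, "n": n, "k": k, "N": N,
             "p": min(p, 1.0), "enrichment_factor": factor,
             "overlap_genes": sorted(overlap)}
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["passes_filter"] = (
        (out["p"] < p_max) & (out["k"] >= min_overlap)
        & (out["enrichment_factor"] > min_factor)
    )
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (cumulative-minimum form)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def cohen_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's kappa between two binary membership vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    n = len(a)
    po = np.mean(a == b)
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1 - pe))


def kappa_cluster(
    memberships: Mapping[str, set[str]],
    pvalues: Mapping[str, float],
    threshold: float = 0.3,
) -> list[dict]:
    """Cluster enriched terms by kappa similarity of their gene memberships.

    Binary membership vectors are taken over the union of the (query-
    overlapping) gene sets; terms join a cluster while the average-linkage
    kappa stays at or above ``threshold`` (i.e. the tree is cut where linkage
    distance 1-kappa exceeds 1-threshold).  Each cluster's representative is
    its most significant member.  Singleton inputs form one cluster.
    """
    term_ids = list(memberships)
    if not term_ids:
        raise ValueError("no terms to cluster")
    universe = sorted(set().union(*memberships.values()))
    mat = np.array([[g in memberships[t] for g in universe] for t in term_ids])
    k = len(term_ids)
    if k == 1:
        labels = np.array([1])
    else:
        dist = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                kap = cohen_kappa(mat[i], mat[j])
                dist[i, j] = dist[j, i] = 1.0 - kap
        Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
        labels = hierarchy.fcluster(Z, t=1.0 - threshold, criterion="distance")
    clusters = []
    for lab in sorted(set(labels)):
        members = [t for t, l in zip(term_ids, labels) if l == lab]
        rep = min(members, key=lambda t: (pvalues.get(t, 1.0), term_ids.index(t)))
        clusters.append({"members": members, "representative": rep})
    clusters.sort(key=lambda c: pvalues.get(c["representative"], 1.0))
    return clusters


def gene_list_annotate(
    hallmark: HallmarkSet,
    region_to_gene: Mapping[str, str],
    gene_lists: Mapping[str, set[str]],
    min_dmrs: int = 3,
) -> pd.DataFrame:
    """Overlap a hallmark's genes with named lists (tumor drivers, HRD genes,
    cancer-hallmark pathways); a pathway is flagged when at least ``min_dmrs``
    hallmark DMRs link to it (boundary inclusive).

    Regions are TSS-anchored, so each DMR maps to its own gene id; no distal
    assignment is attempted.
    """
    dmr_genes: dict[str, list[str]] = {}
    for region in hallmark.region_ids:
        gene = region_to_gene.get(region)
        if gene is not None:
            dmr_genes.setdefault(gene, []).append(region)
    rows = []
    for list_name, genes in gene_lists.items():
        overlap = sorted(set(dmr_genes) & genes)
        linked_dmrs = sorted(r for g in overlap for r in dmr_genes[g])
        rows.append(
            {"list": list_name, "hallmark": hallmark.name,
             "overlap_genes": overlap, "n_genes": len(overlap),
             "n_dmrs": len(linked_dmrs), "linked_dmrs": linked_dmrs,
             "flagged": len(linked_dmrs) >= min_dmrs}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sample clustering


def cluster_samples(matrix: pd.DataFrame):
    """Average-linkage clustering of samples with 1 - Spearman rank correlation.

    ``matrix`` has regions as rows and samples as columns (sqrt-normalized
    methylation values restricted to a hallmark).  Returns the scipy linkage
    matrix and the ordered sample list.  Constant columns make the rank
    correlation undefined and raise.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples and 2 regions")
    constant = [c for c in matrix.columns if matrix[c].nunique() == 1]
    if constant:
        raise ValueError(f"constant sample column(s): {constant}")
    rho = matrix.corr(method="spearman").to_numpy()
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(Z)
    return Z, [matrix.columns[i] for i in order]
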