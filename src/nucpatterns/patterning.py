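"""Promoter patterning quantification, classification and clustering.

Patterning is scored per promoter as the mean-centred cross product between
its occupancy profile (TSS +/- 1 kb, 10-bp bins) and the mean profile over
all active promoters — a raw cross-covariance sum, so the sign carries
meaning: positive scores share the canonical NDR-plus-phased-array shape,
negative scores oppose it.  Promoter classes (active / inactive /
inducible) follow expression rules; CpG islands follow the GC / observed-
expected CpG criterion over TSS +/- 200 bp.  Three hierarchical-clustering
views are provided: samples (mean or per-promoter distances, average
linkage), promoter classes (equal random samples per class), and individual
inducible promoters (Ward linkage, cut into the top three clusters).
Clustering distances use square-root transformed occupancies; the
patterning score itself does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .occupancy import PromoterMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# patterning score

def mean_template(matrix: PromoterMatrix, active_ids) -> np.ndarray:
    """Per-position mean occupancy over the active promoters (the template)."""
    active_ids = list(active_ids)
    if len(active_ids) < 2:
        raise ValueError("need >= 2 active promoters for a template")
    return matrix.mean_profile(active_ids)


def patterning_score(profile: np.ndarray, template: np.ndarray) -> float:
    """Sum of products of the two mean-centred profiles (10-bp bins).

    No variance normalisation: score = sum_i (p_i - mean p)(t_i - mean t).
    A constant profile scores 0 against any template; a profile equal to the
    template scores n * var(template).
    """
    profile = np.asarray(profile, float)
    template = np.asarray(template, float)
    if profile.shape != template.shape:
        raise ValueError("profile and template must share the 10-bp grid")
    return float(np.dot(profile - profile.mean(), template - template.mean()))


def score_matrix(matrix: PromoterMatrix, template: np.ndarray) -> pd.Series:
    """Patterning score of every row against ``template``."""
    centred_t = template - template.mean()
    centred_p = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    return pd.Series(centred_p @ centred_t, index=matrix.promoter_ids, name="patterning")


def split_by_patterning(scores: pd.Series, inducible_ids) -> pd.Series:
    """High/low patterning groups relative to the inducible-set median.

    Threshold = median score over the inducible promoters; strictly greater
    is "high", at or below is "low".
    """
    inducible_ids = list(inducible_ids)
    if len(inducible_ids) < 2:
        raise ValueError("need >= 2 inducible promoters to set the median")
    threshold = float(scores.loc[inducible_ids].median())
    return pd.Series(
        np.where(scores > threshold, "high", "low"), index=scores.index, name="group"
    )


# ---------------------------------------------------------------------------
# promoter classification

@dataclass(frozen=True)
class ClassificationThresholds:
    """Expression thresholds for promoter classes.

    ``induction_diff`` is 1.0 for LPS-stimulated DCs and 0.35 for
    TNF-stimulated fibroblasts (RMA fluorescence differences);
    ``active_fraction_of_mean`` applies to non-stimulated RNA-seq levels;
    ``baf_diff`` applies to knockdown expression differences.
    """

    induction_diff: float = 1.0
    alpha: float = 0.05
    active_fraction_of_mean: float = 0.02
    baf_diff: float = 0.3


def classify_promoters(
    expr: pd.DataFrame, thresholds: ClassificationThresholds | None = None
) -> pd.DataFrame:
    """Label each gene active / inactive / inducible / unclassified.

    inducible: stimulation difference > threshold AND two-sample Student
    t-test (equal variance, two-tailed) on replicate values p < alpha.
    active: non-stimulated level > 0.02 x mean over all genes, not inducible.
    inactive: non-stimulated level == 0, not inducible.  BAF-dependent /
    -inhibited flags come from the knockdown difference beyond +/-0.3.
    Requires ``nonstim_rep*``/``stim_rep*`` replicate columns for the t-test.
    """
    th = thresholds or ClassificationThresholds()
    nonstim_reps = [c for c in expr.columns if c.startswith("nonstim_rep")]
    stim_reps = [c for c in expr.columns if c.startswith("stim_rep")]
    if not nonstim_reps or not stim_reps:
        raise ValueError("replicate columns required for the inducibility t-test")
    out = expr.copy()
    tstat, pval = stats.ttest_ind(
        out[stim_reps].to_numpy(), out[nonstim_reps].to_numpy(),
        axis=1, equal_var=True,
    )
    out["induction_pvalue"] = pval
    inducible = (out["induction_diff"] > th.induction_diff) & (pval < th.alpha)
    mean_level = out["nonstim_level"].mean()
    active = (out["nonstim_level"] > th.active_fraction_of_mean * mean_level) & ~inducible
    inactive = (out["nonstim_level"] == 0) & ~inducible
    label = np.full(len(out), "unclassified", dtype=object)
    label[active.to_numpy()] = "active"
    label[inactive.to_numpy()] = "inactive"
    label[inducible.to_numpy()] = "inducible"
    out["class_label"] = label
    if "baf_diff" in out.columns:
        out["baf_dependent"] = out["baf_diff"] < -th.baf_diff
        out["baf_inhibited"] = out["baf_diff"] > th.baf_diff
    return out


# ---------------------------------------------------------------------------
# CpG islands

def detect_cgi(
    sequence: str, gc_min: float = 0.5, oe_min: float = 0.6, max_n_fraction: float = 0.5
) -> bool | None:
    """CpG-island call on a promoter window (conventionally TSS +/- 200 bp).

    CGI: GC fraction > ``gc_min`` AND observed/expected CpG ratio
    (#CG * length / (#C * #G)) > ``oe_min``.  N bases are excluded from all
    counts and from the effective length; windows with more than
    ``max_n_fraction`` Ns return None (undetermined).
    """
    seq = sequence.upper()
    n_count = seq.count("N")
    if len(seq) == 0 or n_count / len(seq) > max_n_fraction:
        logger.warning("CGI call undetermined: %d/%d Ns", n_count, len(seq))
        return None
    eff_len = len(seq) - n_count
    c, g = seq.count("C"), seq.count("G")
    gc = (c + g) / eff_len
    cg = sum(
        1
        for i in range(len(seq) - 1)
        if seq[i] == "C" and seq[i + 1] == "G"
    )
    if c == 0 or g == 0:
        return False
    oe = cg * eff_len / (c * g)
    return bool(gc > gc_min and oe > oe_min)


def detect_cgi_promoters(
    fasta, promoters: pd.DataFrame, halfwidth: int = 200
) -> pd.Series:
    """CGI flags for all promoters from an indexed FASTA (pyfaidx.Fasta)."""
    flags = {}
    for _, p in promoters.iterrows():
        t = int(p["tss"])
        seq = str(fasta[p["chrom"]][max(t - halfwidth, 0) : t + halfwidth])
        flags[p.get("promoter_id", p.get("gene"))] = detect_cgi(seq)
    return pd.Series(flags, name="cgi")


# ---------------------------------------------------------------------------
# hierarchical clustering

@dataclass
class Dendrogram:
    labels: list
    linkage: np.ndarray  # scipy linkage matrix

    def cut(self, k: int) -> pd.Series:
        """Flat cluster assignment at the k-cluster level."""
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node):
            if node.is_leaf():
                return str(self.labels[node.id])
            l, r = rec(node.get_left()), rec(node.get_right())
            return f"({l}:{node.dist / 2:.6g},{r}:{node.dist / 2:.6g})"

        return rec(tree) + ";"


def _sqrt_euclidean(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.sqrt(a) - np.sqrt(b)))


def cluster_samples(
    matrices: dict[str, PromoterMatrix], mode: str = "mean"
) -> Dendrogram:
    """Average-linkage clustering of samples by sqrt-occupancy distances.

    mode="mean": Euclidean distance between square-rooted mean profiles.
    mode="individual": the same distance computed promoter-by-promoter
    between each sample and its counterpart, then averaged over promoters.
    All samples must share the promoter universe.
    """
    names = list(matrices)
    if len(names) < 2:
        raise ValueError("need >= 2 samples")
    universe = [tuple(matrices[n].promoter_ids) for n in names]
    if len(set(universe)) != 1:
        raise ValueError("samples must share an identical promoter universe")
    n = len(names)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mi, mj = matrices[names[i]], matrices[names[j]]
            if mode == "mean":
                d = _sqrt_euclidean(mi.mean_profile(), mj.mean_profile())
            elif mode == "individual":
                d = float(
                    np.mean(
                        np.linalg.norm(
                            np.sqrt(mi.values) - np.sqrt(mj.values), axis=1
                        )
                    )
                )
            else:
                raise ValueError(f"unknown mode {mode!r}")
            dist[i, j] = dist[j, i] = d
    condensed = dist[np.triu_indices(n, 1)]
    linkage = hierarchy.linkage(condensed, method="average")
    return Dendrogram(labels=names, linkage=linkage)


def cluster_promoter_classes(
    matrix: PromoterMatrix,
    class_labels: pd.Series,
    sample_size: int = 100,
    seed: int = 0,
) -> Dendrogram:
    """Average-linkage tree over promoter classes.

    Draws an equal-sized random sample per class (reduced to the smallest
    class with a warning if needed); the class-to-class distance is the mean
    sqrt-Euclidean distance over all cross-class promoter pairs.
    """
    rng = np.random.default_rng(seed)
    classes = sorted(class_labels.dropna().unique())
    sizes = {c: int((class_labels == c).sum()) for c in classes}
    smallest = min(sizes.values())
    if smallest < sample_size:
        logger.warning("sample_size reduced to smallest class size %d", smallest)
        sample_size = smallest
    picks = {}
    ids = pd.Index(matrix.promoter_ids)
    for c in classes:
        members = class_labels.index[class_labels == c]
        chosen = rng.choice(np.asarray(members), size=sample_size, replace=False)
        picks[c] = np.sqrt(matrix.values[[ids.get_loc(m) for m in chosen]])
    n = len(classes)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = picks[classes[i]], picks[classes[j]]
            # mean of all pairwise promoter distances between the classes
            diff = a[:, None, :] - b[None, :, :]
            dist[i, j] = dist[j, i] = float(
                np.mean(np.linalg.norm(diff, axis=2))
            )
    linkage = hierarchy.linkage(dist[np.triu_indices(n, 1)], method="average")
    return Dendrogram(labels=classes, linkage=linkage)


def cluster_inducible(
    matrix: PromoterMatrix,
    inducible_ids=None,
    k: int = 3,
    weights: np.ndarray | None = None,
) -> tuple[Dendrogram, pd.Series]:
    """Ward clustering of individual inducible promoters; top-``k`` cut.

    Rows are square-root transformed (suppressing aberrantly high isolated
    occupancy values); optional per-position ``weights`` multiply the
    transformed profiles before the Euclidean distance.  Returns the tree
    and the k-cluster assignment.
    """
    if inducible_ids is not None:
        ids = list(inducible_ids)
        idx = [matrix.promoter_ids.index(i) for i in ids]
        rows = matrix.values[idx]
    else:
        ids = list(matrix.promoter_ids)
        rows = matrix.values
    if len(rows) < 2:
        raise ValueError("need >= 2 promoters to cluster")
    x = np.sqrt(rows)
    if weights is not None:
        x = x * np.asarray(weights)[None, :]
    linkage = hierarchy.linkage(x, method="ward", metric="euclidean")
    dend = Dendrogram(labels=ids, linkage=linkage)
    return dend, dend.cut(min(k, len(ids)))
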