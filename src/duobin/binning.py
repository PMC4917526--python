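"""Two-sample differential-coverage genome binning.

Scaffolds from the same genome share (i) a joint coverage signature across
the two samples and (ii) a tetranucleotide composition. Binning proceeds in
three deterministic stages:

1. **Seeding** — density clustering (DBSCAN) of scaffolds in
   ``(log10(cov_1 + eps), log10(cov_2 + eps))`` space. Genomes whose
   abundance differs between conditions occupy distinct points of this
   plane, so clusters correspond to coverage-defined bins.
2. **Refinement** — within each coverage bin, recursive 2-means splitting on
   the leading TNF principal-component scores separates genomes that happen
   to share a coverage signature but differ in composition. A split is only
   accepted when the two children are well separated (centroid distance
   large relative to within-child spread) and both retain a minimum number
   of scaffolds; clusters never merge at this stage.
3. **Link recovery** — scaffolds left unassigned (too short for seeding, or
   density noise) join the bin they are most strongly connected to by
   paired-end links, provided the connection is unambiguous.

Bin labels are canonicalized (ordered by each bin's smallest scaffold id) so
the result is invariant to input row order.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN, KMeans

from .coverage import CoverageMatrix

logger = logging.getLogger(__name__)

NOISE = -1

#: pseudocount added to coverage before log10 so zero-coverage scaffolds
#: remain finite and cluster near the axis
LOG_PSEUDOCOUNT = 0.1


def _canonicalize(labels: pd.Series) -> pd.Series:
    """Relabel clusters 0..k-1 ordered by each cluster's smallest member id."""
    order = {}
    for scaf in sorted(labels.index):
        lab = labels[scaf]
        if lab != NOISE and lab not in order:
            order[lab] = len(order)
    return labels.map(lambda l: order.get(l, NOISE)).astype(int)


def seed_bins(cov: pd.DataFrame, lengths: Mapping[str, int] | pd.Series | None = None,
              min_len: int = 500, eps: float = 0.1, min_samples: int = 5,
              pseudocount: float = LOG_PSEUDOCOUNT) -> pd.Series:
    """Provisional coverage-defined bins.

    ``cov`` is the normalized scaffold x 2-sample coverage table. Scaffolds
    shorter than ``min_len`` are excluded up front (labelled noise) and left
    for link recovery. Returns an integer label per scaffold, -1 = noise.
    """
    if cov.shape[1] != 2:
        raise ValueError(f"expected 2 samples, got {cov.shape[1]}")
    cov = cov.sort_index()
    labels = pd.Series(NOISE, index=cov.index, dtype=int)
    eligible = cov.index
    if lengths is not None:
        lengths = pd.Series(lengths)
        eligible = [s for s in cov.index if lengths.get(s, 0) >= min_len]
    X = np.log10(cov.loc[eligible].to_numpy(dtype=float) + pseudocount)
    if len(eligible) == 0 or not np.any(cov.loc[eligible].to_numpy() > 0):
        logger.warning("seed_bins: no eligible scaffolds with nonzero coverage")
        return labels
    db = DBSCAN(eps=eps, min_samples=min_samples).fit(X)
    labels.loc[eligible] = db.labels_
    return _canonicalize(labels)


def _split_score(X: np.ndarray, part: np.ndarray, centers: np.ndarray) -> float:
    """Centroid separation over pooled within-child RMS distance."""
    within = 0.0
    for k in (0, 1):
        d = X[part == k] - centers[k]
        within += float((d ** 2).sum())
    rms = np.sqrt(within / len(X))
    sep = float(np.linalg.norm(centers[0] - centers[1]))
    return sep / rms if rms > 0 else np.inf


def refine_bins(labels: pd.Series, scores: pd.DataFrame, split_score: float = 3.0,
                min_split_size: int = 5, max_depth: int = 6,
                random_state: int = 0) -> pd.Series:
    """Split multi-genome coverage bins on TNF principal-component scores.

    Recursive 2-means within each seeded bin; a split is kept only when the
    separation score exceeds ``split_score`` and both children have at least
    ``min_split_size`` scaffolds. Scaffolds never move between seeded bins.
    """
    missing = [s for s in labels.index if labels[s] != NOISE and s not in scores.index]
    if missing:
        raise ValueError(f"projection missing for seeded scaffolds: {missing[:5]}")

    out = pd.Series(NOISE, index=labels.index, dtype=int)
    next_label = 0

    def split(ids: list[str], depth: int) -> list[list[str]]:
        if depth >= max_depth or len(ids) < 2 * min_split_size:
            return [ids]
        X = scores.loc[ids].to_numpy(dtype=float)
        km = KMeans(n_clusters=2, n_init=10, random_state=random_state).fit(X)
        part = km.labels_
        sizes = np.bincount(part, minlength=2)
        if sizes.min() < min_split_size:
            return [ids]
        if _split_score(X, part, km.cluster_centers_) < split_score:
            return [ids]
        a = [s for s, p in zip(ids, part) if p == 0]
        b = [s for s, p in zip(ids, part) if p == 1]
        return split(a, depth + 1) + split(b, depth + 1)

    for lab in sorted(set(labels) - {NOISE}):
        ids = sorted(labels.index[labels == lab])
        for group in split(ids, 0):
            out.loc[group] = next_label
            next_label += 1
    return _canonicalize(out)


def recover_linked(labels: pd.Series, links: pd.DataFrame,
                   min_weight: int = 3) -> pd.Series:
    """Assign noise scaffolds to bins via paired-end link weights.

    A noise scaffold joins bin B iff its summed link weight to members of B
    is >= ``min_weight`` and B is the unique maximum; ties leave it
    unassigned. Rounds repeat until a fixpoint — a scaffold recovered in one
    round can anchor its neighbors in the next — with all assignments in a
    round computed against the previous round's labels, so the result does
    not depend on link order.
    """
    if min_weight < 1:
        raise ValueError("min_weight must be >= 1")
    out = labels.copy()
    while True:
        weight_to: dict[str, dict[int, float]] = {}
        for a, b, w in zip(links["scaffold_a"], links["scaffold_b"], links["weight"]):
            for scaf, other in ((a, b), (b, a)):
                if out.get(scaf, NOISE) == NOISE:
                    lab = out.get(other, NOISE)
                    if lab != NOISE:
                        weight_to.setdefault(scaf, {})[lab] = \
                            weight_to.get(scaf, {}).get(lab, 0.0) + float(w)
        changed = False
        for scaf, weights in weight_to.items():
            best = max(weights.values())
            if best < min_weight:
                continue
            winners = [lab for lab, w in weights.items() if w == best]
            if len(winners) == 1:
                out[scaf] = winners[0]
                changed = True
        if not changed:
            return out


def bin_stats(labels: pd.Series, lengths: pd.Series, gc: pd.Series,
              cov: CoverageMatrix) -> pd.DataFrame:
    """Per-bin summary: scaffold count, total length, length-weighted GC%,
    length-weighted mean normalized coverage per sample."""
    norm = cov.require_normalized()
    rows = []
    for lab in sorted(set(labels) - {NOISE}):
        members = sorted(labels.index[labels == lab])
        if not members:
            continue
        L = lengths.loc[members].astype(float)
        total = float(L.sum())
        row = {
            "bin": lab,
            "n_scaffolds": len(members),
            "total_length_bp": int(total),
            "gc_percent": round(100.0 * float((gc.loc[members] * L).sum()) / total, 1),
        }
        for s in cov.samples:
            row[f"coverage_{s}"] = round(
                float((norm.loc[members, s] * L).sum()) / total, 1
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("bin")


def filter_bins(stats: pd.DataFrame, min_completeness: float = 20.0,
                min_size: int = 1_000_000,
                completeness_col: str = "completeness_percent",
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reject bins that are BOTH incomplete (< min_completeness %) and small
    (< min_size bp); either quality alone keeps a bin. Returns (kept,
    rejected-with-reason)."""
    if completeness_col not in stats.columns:
        raise ValueError(f"stats table lacks {completeness_col!r}")
    low = stats[completeness_col] < min_completeness
    small = stats["total_length_bp"] < min_size
    reject = low & small
    rejected = stats.loc[reject].copy()
    rejected["reason"] = (
        f"completeness < {min_completeness}% and total length < {min_size} bp"
    )
    return stats.loc[~reject].copy(), rejected


class DifferentialCoverageBinner(ClusterMixin, BaseEstimator):
    """Differential-coverage scaffold binning with TNF-PCA refinement.

    A scikit-learn style clusterer over the two-sample coverage plane.
    ``fit`` takes the normalized coverage matrix plus optional side inputs
    (scaffold lengths, TNF PCA scores, paired-end link graph) and exposes the
    final labelling as ``labels_``.

    Parameters
    ----------
    eps, min_samples : DBSCAN parameters in log10-coverage space.
    min_len : scaffolds shorter than this are excluded from seeding and left
        to link recovery (500 bp by the assembly convention).
    refine : whether to run composition refinement (needs ``pca_scores``).
    split_score, min_split_size : refinement split acceptance rule.
    link_min_weight : minimum summed link weight for recovery.
    random_state : seed for the refinement k-means.
    """

    def __init__(self, eps: float = 0.1, min_samples: int = 5, min_len: int = 500,
                 pseudocount: float = LOG_PSEUDOCOUNT, refine: bool = True,
                 split_score: float = 3.0, min_split_size: int = 5,
                 link_min_weight: int = 3, random_state: int = 0):
        self.eps = eps
        self.min_samples = min_samples
        self.min_len = min_len
        self.pseudocount = pseudocount
        self.refine = refine
        self.split_score = split_score
        self.min_split_size = min_split_size
        self.link_min_weight = link_min_weight
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None, *, lengths: pd.Series | None = None,
            pca_scores: pd.DataFrame | None = None,
            links: pd.DataFrame | None = None):
        labels = seed_bins(X, lengths=lengths, min_len=self.min_len, eps=self.eps,
                           min_samples=self.min_samples, pseudocount=self.pseudocount)
        self.seed_labels_ = labels.copy()
        if self.refine and pca_scores is not None:
            labels = refine_bins(labels, pca_scores, split_score=self.split_score,
                                 min_split_size=self.min_split_size,
                                 random_state=self.random_state)
        if links is not None and len(links):
            labels = recover_linked(labels, links, min_weight=self.link_min_weight)
        self.labels_ = labels
        self.n_bins_ = int(len(set(labels) - {NOISE}))
        return self

    def fit_predict(self, X, y=None, **fit_params) -> pd.Series:
        return self.fit(X, y, **fit_params).labels_


def evaluate_against_truth(labels: pd.Series, truth: Mapping[str, str],
                           lengths: pd.Series,
                           purity_threshold: float = 0.9) -> pd.DataFrame:
    """Score recovered bins against a known scaffold -> genome assignment.

    For each bin, purity is the bp fraction of its majority genome. A genome
    counts as recovered when some bin's majority genome is it and that bin's
    purity is >= ``purity_threshold``. Returns a per-genome table with
    columns best_bin, purity, recall_bp, recovered.
    """
    truth = pd.Series(truth)
    genomes = sorted(truth.unique())
    bin_major: dict[int, tuple[str, float]] = {}
    for lab in sorted(set(labels) - {NOISE}):
        members = labels.index[labels == lab]
        bp = lengths.loc[members].groupby(truth.loc[members]).sum()
        major = bp.idxmax()
        bin_major[lab] = (major, float(bp[major] / bp.sum()))

    rows = []
    genome_bp = lengths.groupby(truth.loc[lengths.index]).sum()
    for g in genomes:
        candidates = [
            (lab, purity) for lab, (major, purity) in bin_major.items() if major == g
        ]
        if candidates:
            best_lab, purity = max(
                candidates,
                key=lambda t: lengths.loc[labels.index[labels == t[0]]].sum(),
            )
            members = labels.index[labels == best_lab]
            captured = float(lengths.loc[members][truth.loc[members] == g].sum())
            recall = captured / float(genome_bp[g])
        else:
            best_lab, purity, recall = NOISE, 0.0, 0.0
        rows.append({
            "genome": g, "best_bin": best_lab, "purity": round(purity, 4),
            "recall_bp": round(recall, 4),
            "recovered": bool(candidates) and purity >= purity_threshold,
        })
    return pd.DataFrame(rows).set_index("genome")
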