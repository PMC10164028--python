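"""Post-hoc model interrogation: which edges, networks and hemispheres drive
the decoding.

Selection probability = fraction of CV repetitions in which an edge survived
fold-wise ANOVA selection.  Network relevance averages these probabilities
over within- and between-network edge blocks.  Edges selected in *every*
repetition ("stable", probability 1) carry the weight analysis: per-fold
L2-normalized SVM weights are averaged, their sign attributes each edge to FA
(positive) or OM (negative), and one-sample t-tests (fold weights as
replicates, Bonferroni-corrected) assess departure from zero.  Hemispheric
statistics compare intra-left vs intra-right stable edges by weight magnitude
(one-sided Mann-Whitney) and by count (permutation of ROI hemisphere labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import DecodingDataset, matrix_from_vector
from .decoding import CVResult, anova_f_scores
from .inference import bonferroni, mann_whitney
from .parcellation import EdgeTable, ParcellationTable, classify_hemisphere
from .util import ConfigurationError, ValidationError, log, rng_stream


@dataclass
class SelectionProbabilityMatrix:
    matrix: np.ndarray            # symmetric ROI x ROI, entries in [0, 1]
    per_edge: np.ndarray          # (n_edges,), aligned to EdgeTable order
    n_repetitions: int

    def __post_init__(self) -> None:
        if np.any(self.per_edge < 0) or np.any(self.per_edge > 1):
            raise ValidationError("selection probabilities outside [0, 1]")


@dataclass
class NetworkRelevance:
    networks: tuple[str, ...]
    block_matrix: np.ndarray      # network x network mean selection probability
    per_network: np.ndarray       # mean over the network's row of blocks

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.block_matrix, index=self.networks,
                            columns=self.networks)


@dataclass
class WeightMap:
    edge_ids: np.ndarray
    mean_weight: np.ndarray       # mean per-fold normalized weight
    condition: np.ndarray         # "FA" (positive) / "OM" (negative)
    t_stat: np.ndarray
    p_adj: np.ndarray             # Bonferroni over stable edges
    weight_norm: str

    def to_frame(self, edges: EdgeTable) -> pd.DataFrame:
        i, j = edges.roi_i[self.edge_ids], edges.roi_j[self.edge_ids]
        return pd.DataFrame(
            {"edge_id": self.edge_ids, "roi_i": i, "roi_j": j,
             "network_i": edges.network_i[self.edge_ids],
             "network_j": edges.network_j[self.edge_ids],
             "hemi_class": edges.hemi_class[self.edge_ids],
             "mean_weight": self.mean_weight, "condition": self.condition,
             "t": self.t_stat, "p_adj": self.p_adj})


@dataclass
class HemisphericStats:
    edges_by_class: dict[str, np.ndarray]
    counts: dict[str, int]
    mw_U: float | None = None      # |weights| intra_left vs intra_right
    mw_p: float | None = None
    count_p: dict[str, float] = field(default_factory=dict)
    note: str = ""


def selection_probability(cv: CVResult, edges: EdgeTable) -> SelectionProbabilityMatrix:
    """Per-edge fraction of repetitions in which the edge was selected."""
    if not cv.folds:
        raise ValidationError("CV result has no folds")
    counts = np.zeros(cv.n_edges)
    for f in cv.folds:
        counts[f.selected_edges] += 1
    per_edge = counts / cv.n_repetitions
    return SelectionProbabilityMatrix(
        matrix=matrix_from_vector(per_edge, edges), per_edge=per_edge,
        n_repetitions=cv.n_repetitions)


def network_relevance(sp: SelectionProbabilityMatrix,
                      parcellation: ParcellationTable,
                      edges: EdgeTable) -> NetworkRelevance:
    """Mean selection probability per within/between-network edge block.

    The per-network scalar averages the network's row of block means (its
    within block plus every between block), i.e. the probability that a
    connection involving that network is selected.  A single-ROI network has
    no within edges; its diagonal block is NaN.
    """
    if sp.per_edge.shape[0] != edges.n_edges:
        raise ValidationError("probability vector does not match edge table")
    nets = parcellation.networks
    idx = {n: k for k, n in enumerate(nets)}
    n_net = len(nets)
    sums = np.zeros((n_net, n_net))
    counts = np.zeros((n_net, n_net))
    a = np.vectorize(idx.get)(edges.network_i)
    b = np.vectorize(idx.get)(edges.network_j)
    for e in range(edges.n_edges):
        i, j = min(a[e], b[e]), max(a[e], b[e])
        sums[i, j] += sp.per_edge[e]
        counts[i, j] += 1
    with np.errstate(invalid="ignore"):
        block = sums / counts
    block = np.where(counts > 0, block, np.nan)
    iu = np.triu_indices(n_net)
    full = np.full((n_net, n_net), np.nan)
    full[iu] = block[iu]
    full[(iu[1], iu[0])] = block[iu]
    per_network = np.nanmean(full, axis=1)
    return NetworkRelevance(networks=nets, block_matrix=full,
                            per_network=per_network)


def stable_edges(sp: SelectionProbabilityMatrix, threshold: float = 1.0) -> np.ndarray:
    """Edge ids with selection probability >= threshold, ascending order."""
    out = np.nonzero(sp.per_edge >= threshold)[0]
    if out.size == 0:
        log.warning("stable_edges: no edge reaches probability %.3g", threshold)
    return out


def _normalize(w: np.ndarray, how: str) -> np.ndarray:
    if how == "l2":
        norm = np.linalg.norm(w)
        return w / norm if norm > 0 else w
    if how == "max_abs":
        m = np.abs(w).max()
        return w / m if m > 0 else w
    if how == "none":
        return w
    raise ConfigurationError(f"unknown weight_norm {how!r}")


def weight_map(cv: CVResult, stable: np.ndarray,
               weight_norm: str = "l2") -> WeightMap:
    """Mean normalized classifier weight per stable edge, with FA/OM tags.

    Each fold's weight vector (over its own selected edges) is normalized,
    then each stable edge's normalized weight is collected across the folds
    containing it (all folds, at the probability-1 threshold) and averaged.
    Sign > 0 tags the edge FA, < 0 tags it OM; a one-sample t-test across
    folds (Bonferroni over stable edges) quantifies departure from zero.
    Fold weights are overlapping-resample replicates; the t-test replicates
    the procedure of interest and inherits its dependence caveat.
    """
    stable = np.asarray(stable, dtype=int)
    if stable.size == 0:
        return WeightMap(edge_ids=stable, mean_weight=np.empty(0),
                         condition=np.empty(0, dtype=object),
                         t_stat=np.empty(0), p_adj=np.empty(0),
                         weight_norm=weight_norm)
    per_edge_weights: list[list[float]] = [[] for _ in stable]
    pos = {int(e): k for k, e in enumerate(stable)}
    for f in cv.folds:
        w = _normalize(f.weights, weight_norm)
        sel = f.selected_edges
        for e_local, e in enumerate(sel):
            k = pos.get(int(e))
            if k is not None:
                per_edge_weights[k].append(float(w[e_local]))
    missing = [int(stable[k]) for k, lst in enumerate(per_edge_weights)
               if len(lst) < cv.n_repetitions]
    if missing:
        log.warning("weight_map: %d edge(s) absent from some folds "
                    "(threshold < 1?); averaging over available folds",
                    len(missing))
    mean_w = np.array([np.mean(lst) for lst in per_edge_weights])
    t_stat = np.empty(stable.size)
    p_raw = np.empty(stable.size)
    for k, lst in enumerate(per_edge_weights):
        arr = np.asarray(lst)
        if arr.size < 2 or arr.std(ddof=1) == 0:
            t_stat[k] = np.inf if mean_w[k] != 0 else 0.0
            p_raw[k] = 0.0 if mean_w[k] != 0 else 1.0
        else:
            res = stats.ttest_1samp(arr, 0.0)
            t_stat[k], p_raw[k] = float(res.statistic), float(res.pvalue)
    zero = mean_w == 0
    if zero.any():
        log.warning("weight_map: %d stable edge(s) with exactly zero mean "
                    "weight excluded from FA/OM tagging", int(zero.sum()))
    condition = np.where(mean_w > 0, "FA", "OM").astype(object)
    condition[zero] = "untagged"
    return WeightMap(edge_ids=stable, mean_weight=mean_w, condition=condition,
                     t_stat=t_stat, p_adj=bonferroni(p_raw, stable.size),
                     weight_norm=weight_norm)


def relevant_feature_fstats(dataset: DecodingDataset,
                            stable: np.ndarray) -> pd.DataFrame:
    """Whole-dataset one-way ANOVA per stable edge, df = (1, n_samples - 2)."""
    stable = np.asarray(stable, dtype=int)
    if stable.size == 0:
        raise ValidationError("stable edge list is empty")
    F = anova_f_scores(dataset.X[:, stable], dataset.y)
    df2 = dataset.n_samples - 2
    p = stats.f.sf(F, 1, df2)
    return pd.DataFrame({"edge_id": stable, "F": F, "p": p, "df1": 1, "df2": df2})


def hemispheric_analysis(wm: WeightMap, edges: EdgeTable,
                         parcellation: ParcellationTable,
                         n_perm: int = 200, seed: int = 0) -> HemisphericStats:
    """Hemispheric structure of the stable-edge weight map.

    Stable edges partition into intra-left / intra-right / inter (midline
    endpoints -> other, excluded from the tests).  |mean weight| left vs
    right is compared one-sided (left > right) by Mann-Whitney; the intra-
    hemispheric edge *counts* are tested by permuting the ROI hemisphere
    label vector and recounting, with add-one Monte-Carlo p-values.
    """
    classes = edges.hemi_class[wm.edge_ids]
    by_class = {c: wm.edge_ids[classes == c]
                for c in ("intra_left", "intra_right", "inter", "other")}
    counts = {c: int(v.size) for c, v in by_class.items()}
    out = HemisphericStats(edges_by_class=by_class, counts=counts)
    if wm.edge_ids.size == 0:
        out.note = "empty stable set; tests skipped"
        return out
    left_w = np.abs(wm.mean_weight[classes == "intra_left"])
    right_w = np.abs(wm.mean_weight[classes == "intra_right"])
    if left_w.size and right_w.size:
        mw = mann_whitney(left_w, right_w, alternative="greater")
        out.mw_U, out.mw_p = mw.U, mw.p_value
    else:
        out.note = "a hemisphere has no intra edges; magnitude test skipped"
    hemis = parcellation.hemisphere_labels
    i_idx = edges.roi_i[wm.edge_ids]
    j_idx = edges.roi_j[wm.edge_ids]
    rng = rng_stream(seed, "hemisphere-permutation")
    perm_counts = {"intra_left": np.empty(n_perm, dtype=int),
                   "intra_right": np.empty(n_perm, dtype=int)}
    for p in range(n_perm):
        perm = hemis[rng.permutation(hemis.size)]
        cls = np.array([classify_hemisphere(perm[a], perm[b])
                        for a, b in zip(i_idx, j_idx)])
        perm_counts["intra_left"][p] = int((cls == "intra_left").sum())
        perm_counts["intra_right"][p] = int((cls == "intra_right").sum())
    for side in ("intra_left", "intra_right"):
        out.count_p[side] = float(
            ((perm_counts[side] >= counts[side]).sum() + 1) / (n_perm + 1))
    return out
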