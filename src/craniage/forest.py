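"""Regression forest mapping surface-anchored features to gestational age.

Training follows the classic variance-reduction recipe: each tree sees
a bagged subset of examples; at each node ``m`` feature descriptors are
drawn at random, each is evaluated on the node's examples, thresholds
are scanned over inter-decile midpoints of the scores, and the split
maximising the differential-entropy information gain

    Ig = log sigma^2(parent) - sum_{i in L,R} w_i log sigma^2(child_i)

is kept (ages modelled as univariate Gaussians; natural log; population
variances with a small floor).  Leaves store the Gaussian (mean,
variance) of the ages that reached them.

Prediction routes an unseen (image, surface) pair down every tree and
averages only the leaf means whose variance is below ``sigma_max2``
(default 1.0 GW^2); when no leaf passes the filter the mean over all
reached leaves is used and flagged.  Forests are per-hemisphere.

Also provided: RMSE evaluation, per-level feature-selection profiles,
tree-traversal path statistics, appearance "maturation" heat maps,
quadratic error-margin (delta_w) analysis, and a longitudinal
consistency check for repeat-scan subjects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh

from . import features as fe
from .features import (FeatureDescriptor, HemisphereSampling, TTPlaneDef,
                       sample_feature_descriptor)

VAR_FLOOR = 1e-6   # GW^2, guards log of zero-variance children
FORMAT_VERSION = 1


# --------------------------------------------------------------------------
# training examples
# --------------------------------------------------------------------------

@dataclass(eq=False)
class TrainingExample:
    """One (preprocessed image, fitted surface, age) triple."""

    volume: np.ndarray
    spacing: float
    hs: HemisphereSampling
    mesh: trimesh.Trimesh                 # fitted inner-skull surface
    surface_points: np.ndarray            # dense points anchoring Ptt
    tt: TTPlaneDef
    age: float                            # GW
    hemisphere: str
    _cache: dict = field(default_factory=dict, repr=False)

    def evaluate(self, d: FeatureDescriptor) -> float:
        if d.kind in fe.APPEARANCE_KINDS:
            return fe.eval_appearance(self.volume, self.spacing,
                                      self.hs, d)[0]
        if d.kind in fe.SIZE_KINDS:
            return fe.eval_local_size(self.hs, d)
        if "inner_hc" not in self._cache:
            self._cache["inner_hc"] = fe.eval_inner_hc(
                self.mesh, self.surface_points, self.tt)
        return self._cache["inner_hc"]


# --------------------------------------------------------------------------
# split criterion
# --------------------------------------------------------------------------

def information_gain(ages_parent, ages_left, ages_right,
                     var_floor: float = VAR_FLOOR) -> float:
    """Differential-entropy gain of a binary age split.

    Population variances (floored), child weights w_i = |child|/|parent|,
    natural logarithm.  An empty child yields -inf (split rejected).
    """
    p = np.asarray(ages_parent, float)
    l = np.asarray(ages_left, float)
    r = np.asarray(ages_right, float)
    if len(l) == 0 or len(r) == 0:
        return -math.inf
    if len(l) + len(r) != len(p):
        raise ValueError("children must partition the parent")

    def lv(a):
        return math.log(max(float(np.var(a)), var_floor))

    wl = len(l) / len(p)
    wr = len(r) / len(p)
    return lv(p) - wl * lv(l) - wr * lv(r)


def _decile_midpoints(scores: np.ndarray) -> np.ndarray:
    """The 10 midpoints between consecutive deciles of the scores."""
    edges = np.quantile(scores, np.linspace(0.0, 1.0, 11))
    return 0.5 * (edges[:-1] + edges[1:])


def best_split(examples: Sequence[TrainingExample], ages: np.ndarray,
               m: int, rng: np.random.Generator,
               enabled_banks: Sequence[str], min_samples: int,
               hemisphere: str):
    """Search m random descriptors x decile-midpoint thresholds for the
    maximum-gain split.  Returns (descriptor, threshold, gain,
    left_mask) or None when every candidate is degenerate.  Ties keep
    the first-encountered candidate (strict improvement required)."""
    n_points = len(examples[0].hs.points)
    best = None
    best_gain = -math.inf
    for _ in range(m):
        d = sample_feature_descriptor(rng, enabled_banks, n_points,
                                      hemisphere=hemisphere)
        scores = np.array([ex.evaluate(d) for ex in examples])
        if np.allclose(scores, scores[0]):
            continue
        for tau in _decile_midpoints(scores):
            left = scores < tau
            nl = int(left.sum())
            if nl < min_samples or len(scores) - nl < min_samples:
                continue
            g = information_gain(ages, ages[left], ages[~left])
            if g > best_gain:
                best_gain = g
                best = (d, float(tau), g, left)
    return best


# --------------------------------------------------------------------------
# forest structures
# --------------------------------------------------------------------------

@dataclass
class LeafNode:
    mean: float
    variance: float
    count: int

    def to_dict(self):
        return dict(type="leaf", mean=self.mean, variance=self.variance,
                    count=self.count)


@dataclass
class SplitNode:
    feature: FeatureDescriptor
    threshold: float
    gain: float
    left: "SplitNode | LeafNode"
    right: "SplitNode | LeafNode"

    def to_dict(self):
        return dict(type="split", feature=self.feature.to_dict(),
                    threshold=self.threshold, gain=self.gain,
                    left=self.left.to_dict(), right=self.right.to_dict())


def _node_from_dict(d):
    if d["type"] == "leaf":
        return LeafNode(d["mean"], d["variance"], d["count"])
    return SplitNode(FeatureDescriptor.from_dict(d["feature"]),
                     d["threshold"], d["gain"],
                     _node_from_dict(d["left"]), _node_from_dict(d["right"]))


@dataclass
class ForestHyperparams:
    n_trees: int = 20
    max_depth: int = 15
    candidates_per_node: int = 200
    min_samples: int = 5
    min_gain: float = 1e-3
    sigma_max2: float = 1.0          # GW^2
    bagging_fraction: float = 0.67   # with replacement
    seed: int = 0

    def __post_init__(self):
        if min(self.n_trees, self.max_depth, self.candidates_per_node,
               self.min_samples) < 1:
            raise ValueError("forest hyperparameters must be positive")
        if not 0 < self.bagging_fraction <= 1:
            raise ValueError("bagging_fraction must be in (0, 1]")


@dataclass
class RegressionForest:
    trees: list
    hemisphere: str
    hyperparams: ForestHyperparams
    enabled_banks: tuple

    def to_json(self) -> str:
        return json.dumps(dict(
            format_version=FORMAT_VERSION,
            hemisphere=self.hemisphere,
            hyperparams=asdict(self.hyperparams),
            enabled_banks=list(self.enabled_banks),
            trees=[t.to_dict() for t in self.trees]))

    @classmethod
    def from_json(cls, text: str) -> "RegressionForest":
        d = json.loads(text)
        ver = d.get("format_version")
        if ver != FORMAT_VERSION:
            raise ValueError(f"model format version {ver} not supported "
                             f"(expected {FORMAT_VERSION})")
        return cls(trees=[_node_from_dict(t) for t in d["trees"]],
                   hemisphere=d["hemisphere"],
                   hyperparams=ForestHyperparams(**d["hyperparams"]),
                   enabled_banks=tuple(d["enabled_banks"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "RegressionForest":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _grow(examples, ages, depth, hp, rng, banks, hemisphere):
    def leaf():
        return LeafNode(float(np.mean(ages)),
                        float(max(np.var(ages), VAR_FLOOR)),
                        int(len(ages)))

    if depth >= hp.max_depth or len(ages) < 2 * hp.min_samples:
        return leaf()
    found = best_split(examples, ages, hp.candidates_per_node, rng, banks,
                       hp.min_samples, hemisphere)
    if found is None:
        return leaf()
    d, tau, gain, left = found
    if gain <= hp.min_gain:
        return leaf()
    exl = [ex for ex, m in zip(examples, left) if m]
    exr = [ex for ex, m in zip(examples, left) if not m]
    return SplitNode(d, tau, gain,
                     _grow(exl, ages[left], depth + 1, hp, rng, banks,
                           hemisphere),
                     _grow(exr, ages[~left], depth + 1, hp, rng, banks,
                           hemisphere))


def train_forest(examples: Sequence[TrainingExample],
                 hp: ForestHyperparams | None = None,
                 enabled_banks: Sequence[str] = fe.ALL_KINDS
                 ) -> RegressionForest:
    """Train a per-hemisphere forest on bagged example subsets."""
    if hp is None:
        hp = ForestHyperparams()
    if len(examples) == 0:
        raise ValueError("empty training cohort")
    hemis = {ex.hemisphere for ex in examples}
    if len(hemis) != 1:
        raise ValueError(f"mixed hemispheres in cohort: {sorted(hemis)}; "
                         "train one forest per hemisphere")
    hemisphere = hemis.pop()
    ages = np.array([ex.age for ex in examples])
    n = len(examples)
    trees = []
    seeds = np.random.SeedSequence(hp.seed).spawn(hp.n_trees)
    for t in range(hp.n_trees):
        rng = np.random.default_rng(seeds[t])
        size = max(1, int(round(hp.bagging_fraction * n)))
        bag = rng.integers(0, n, size=size)
        trees.append(_grow([examples[i] for i in bag], ages[bag], 0, hp,
                           rng, tuple(enabled_banks), hemisphere))
    return RegressionForest(trees=trees, hemisphere=hemisphere,
                            hyperparams=hp,
                            enabled_banks=tuple(enabled_banks))


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------

@dataclass
class Prediction:
    age: float                     # GW
    used_leaves: int               # |A|
    per_tree: list                 # (mean, variance) per tree
    fallback_used: bool
    path_lengths: list


def _route(node, example):
    depth = 0
    while isinstance(node, SplitNode):
        node = (node.left if example.evaluate(node.feature) < node.threshold
                else node.right)
        depth += 1
    return node, depth


def predict(forest: RegressionForest, example: TrainingExample,
            sigma_max2: float | None = None) -> Prediction:
    """Variance-filtered forest prediction of gestational age."""
    if example.hemisphere != forest.hemisphere:
        raise ValueError(f"example hemisphere {example.hemisphere!r} does "
                         f"not match forest {forest.hemisphere!r}")
    if sigma_max2 is None:
        sigma_max2 = forest.hyperparams.sigma_max2
    per_tree, paths = [], []
    for tree in forest.trees:
        leaf, depth = _route(tree, example)
        per_tree.append((leaf.mean, leaf.variance))
        paths.append(depth)
    means = np.array([m for m, _ in per_tree])
    varis = np.array([v for _, v in per_tree])
    keep = varis < sigma_max2
    if np.any(keep):
        return Prediction(float(means[keep].mean()), int(keep.sum()),
                          per_tree, False, paths)
    # no leaf satisfies the variance filter: fall back to the plain
    # forest mean and flag it
    return Prediction(float(means.mean()), 0, per_tree, True, paths)


def rmse(predictions, truths) -> float:
    """Root-mean-squared prediction error in GW (days = 7 * GW)."""
    p = np.asarray(predictions, float)
    t = np.asarray(truths, float)
    if len(p) != len(t) or len(p) == 0:
        raise ValueError("predictions and truths must be equal, non-empty")
    return float(np.sqrt(np.mean((p - t) ** 2)))


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------

def _walk(node, depth=0):
    yield node, depth
    if isinstance(node, SplitNode):
        yield from _walk(node.left, depth + 1)
        yield from _walk(node.right, depth + 1)


def feature_selection_profile(forest: RegressionForest) -> pd.DataFrame:
    """Per-level selection frequency of each feature kind among split
    nodes, normalised by the number of split nodes at that level (rows
    sum to 1)."""
    counts: dict[int, dict[str, int]] = {}
    for tree in forest.trees:
        for node, depth in _walk(tree):
            if isinstance(node, SplitNode):
                counts.setdefault(depth, {}).setdefault(
                    node.feature.kind, 0)
                counts[depth][node.feature.kind] += 1
    rows = []
    for depth in sorted(counts):
        nd = sum(counts[depth].values())
        row = {"depth": depth, "n_split_nodes": nd}
        for kind in fe.ALL_KINDS:
            row[kind] = counts[depth].get(kind, 0) / nd
        rows.append(row)
    return pd.DataFrame(rows)


def traversal_path_lengths(forest: RegressionForest,
                           examples: Sequence[TrainingExample]
                           ) -> pd.DataFrame:
    """Root-to-leaf path length per example (mean over trees), with the
    example's true age for age-trend analysis."""
    rows = []
    for ex in examples:
        pr = predict(forest, ex)
        rows.append(dict(age=ex.age,
                         mean_path=float(np.mean(pr.path_lengths)),
                         max_path=int(np.max(pr.path_lengths))))
    return pd.DataFrame(rows)


def maturation_map(forest: RegressionForest, depth: int,
                   reference: TrainingExample) -> tuple[np.ndarray, bool]:
    """Heat map of appearance-VOI footprints at one forest level.

    For each appearance split node at ``depth`` the voxels its VOI
    samples on the reference example are incremented; the map is then
    normalised by the number of split nodes at that level.  Returns
    (map, empty_flag).
    """
    shape = reference.volume.shape
    acc = np.zeros(shape)
    nd = 0
    n_app = 0
    for tree in forest.trees:
        for node, d in _walk(tree):
            if d != depth or not isinstance(node, SplitNode):
                continue
            nd += 1
            desc = node.feature
            if desc.kind not in fe.APPEARANCE_KINDS:
                continue
            n_app += 1
            for pi in ([desc.point_index, desc.point_index2]
                       if desc.kind == "binary_context"
                       else [desc.point_index]):
                centre, axis, side = fe._voi_centre_axis(
                    reference.hs, desc, pi)
                _, _, _, _, mm = fe._voi_samples(
                    reference.volume, reference.spacing, centre, axis, side)
                vox = np.round(mm / reference.spacing).astype(int)
                ok = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
                np.add.at(acc, tuple(vox[ok].T), 1.0)
    if nd == 0:
        return acc, True
    return acc / nd, n_app == 0


# --------------------------------------------------------------------------
# error-margin (delta_w) analysis
# --------------------------------------------------------------------------

@dataclass
class ErrorMargin:
    zeta_plus: np.ndarray     # quadratic coefficients, days vs GW
    zeta_minus: np.ndarray
    age_grid: np.ndarray      # GW
    delta_w: np.ndarray       # days, >= 0 on the grid

    def delta_at(self, age) -> np.ndarray:
        return np.abs(np.polyval(self.zeta_plus, age)
                      - np.polyval(self.zeta_minus, age))


def error_margin(predictions, truths,
                 age_grid: np.ndarray | None = None,
                 min_group: int = 6) -> ErrorMargin:
    """Quadratic error-margin analysis of age predictions.

    Residuals (pred - truth, converted to days) are split by sign into
    over- and under-estimations; a quadratic in true age is fit to each
    group and delta_w(age) = |zeta+(age) - zeta-(age)| reported on the
    age grid.
    """
    p = np.asarray(predictions, float)
    t = np.asarray(truths, float)
    resid_days = (p - t) * 7.0
    pos = resid_days > 0
    neg = resid_days < 0
    if pos.sum() < min_group or neg.sum() < min_group:
        raise ValueError(
            f"need at least {min_group} over- and under-estimations for "
            f"the quadratic fits (got {int(pos.sum())}/{int(neg.sum())}); "
            "evaluate on more test examples")
    zp = np.polyfit(t[pos], resid_days[pos], 2)
    zm = np.polyfit(t[neg], resid_days[neg], 2)
    if age_grid is None:
        age_grid = np.linspace(18.0, 34.0, 33)
    dw = np.abs(np.polyval(zp, age_grid) - np.polyval(zm, age_grid))
    return ErrorMargin(zp, zm, age_grid, dw)


def longitudinal_consistency(sessions: pd.DataFrame) -> dict:
    """Interval agreement for subjects scanned at multiple time points.

    ``sessions`` needs columns (subject, true_age, predicted_age).
    Reports the mean absolute error of predicted vs true inter-scan
    intervals and the fraction of subjects whose predicted trajectory
    is monotone in scan order.  Single-session subjects are skipped.
    """
    errs, monotone, skipped = [], [], 0
    for _, grp in sessions.groupby("subject"):
        if len(grp) < 2:
            skipped += 1
            continue
        g = grp.sort_values("true_age")
        true_iv = np.diff(g["true_age"].to_numpy())
        pred_iv = np.diff(g["predicted_age"].to_numpy())
        errs.extend(np.abs(pred_iv - true_iv))
        monotone.append(bool(np.all(pred_iv > 0)))
    if not errs:
        raise ValueError("no subject has two or more sessions")
    return dict(mean_interval_error=float(np.mean(errs)),
                monotone_fraction=float(np.mean(monotone)),
                n_subjects=len(monotone), n_skipped=skipped)
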