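"""Continuous pharmacophore subset scoring.

A pharmacophore hypothesis is a set of typed feature points (donor,
acceptor, aromatic, ...) at 3D positions with tolerance radii.  A
conformer matches a sub-hypothesis if some injective, type-respecting
assignment of its features to the sub-hypothesis points admits a single
rigid (rotation + translation) superposition placing every assigned
feature within its point's tolerance radius.

Boolean matching is extended to a continuous ranking score by
evaluating all sub-hypotheses of size >= min_size: with n hypothesis
points, K the largest subset size matched by any conformer and m_K the
number of matched size-K subsets,

    score = (K + m_K / C(n, K) - 1) / n        (0 if K < min_size)

so compounds are ranked first by the deepest partial match and, within
a depth, by the breadth of distinct matches; only a full-hypothesis
match reaches 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

FEATURE_TYPES = ("donor", "acceptor", "aromatic", "hydrophobic", "positive", "negative")


@dataclass(frozen=True)
class PharmacophorePoint:
    feature_type: str
    position: tuple[float, float, float]
    tolerance_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")
        if self.tolerance_radius <= 0:
            raise ValueError("tolerance_radius must be > 0")


@dataclass(frozen=True)
class PharmacophoreHypothesis:
    points: tuple[PharmacophorePoint, ...]

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValueError("hypothesis needs at least one point")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def coords(self) -> np.ndarray:
        return np.array([p.position for p in self.points], dtype=float)


@dataclass(frozen=True)
class ConformerFeatures:
    """Typed feature points of one conformer of one compound."""

    compound_id: str
    features: tuple[tuple[str, tuple[float, float, float]], ...]


def enumerate_subsets(
    hypothesis: PharmacophoreHypothesis, min_size: int
) -> list[PharmacophoreHypothesis]:
    """All sub-hypotheses of size >= min_size (count = sum_k C(n, k))."""
    n = hypothesis.n_points
    if not 1 <= min_size <= n:
        raise ValueError(f"min_size must be in [1, {n}]")
    subs = []
    for k in range(min_size, n + 1):
        for idx in combinations(range(n), k):
            subs.append(PharmacophoreHypothesis(tuple(hypothesis.points[i] for i in idx)))
    return subs


def _kabsch_residuals(ref: np.ndarray, mov: np.ndarray) -> np.ndarray:
    """Per-point distances after optimal rigid superposition of mov onto ref."""
    rc, mc = ref.mean(axis=0), mov.mean(axis=0)
    p, q = ref - rc, mov - mc
    h = q.T @ p
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    aligned = q @ rot + rc
    return np.linalg.norm(aligned - ref, axis=1)


def match_subset(
    sub_hypothesis: PharmacophoreHypothesis, conformer: ConformerFeatures
) -> bool:
    """True iff the conformer matches every point of the sub-hypothesis.

    Correspondence search over type-compatible feature assignments with
    pairwise-distance pruning, followed by Kabsch superposition and a
    per-point tolerance check.
    """
    pts = sub_hypothesis.points
    k = len(pts)
    feats = conformer.features
    cand = [
        [i for i, (t, _) in enumerate(feats) if t == p.feature_type] for p in pts
    ]
    if any(not c for c in cand):
        return False
    hyp_xyz = sub_hypothesis.coords()
    feat_xyz = np.array([xyz for _, xyz in feats], dtype=float)
    hyp_d = np.linalg.norm(hyp_xyz[:, None, :] - hyp_xyz[None, :, :], axis=-1)
    feat_d = np.linalg.norm(feat_xyz[:, None, :] - feat_xyz[None, :, :], axis=-1)
    tol = np.array([p.tolerance_radius for p in pts])

    def search(i: int, assigned: list[int]) -> bool:
        if i == k:
            res = _kabsch_residuals(hyp_xyz, feat_xyz[assigned])
            return bool(np.all(res <= tol + 1e-9))
        for f in cand[i]:
            if f in assigned:
                continue
            ok = all(
                abs(feat_d[f, assigned[j]] - hyp_d[i, j]) <= tol[i] + tol[j] + 1e-9
                for j in range(i)
            )
            if ok and search(i + 1, assigned + [f]):
                return True
        return False

    return search(0, [])


def continuous_score(
    hypothesis: PharmacophoreHypothesis,
    conformers: list[ConformerFeatures],
    min_size: int = 3,
) -> float:
    """Continuous [0, 1] subset-match score over a compound's conformers.

    A subset counts as matched if any conformer matches it.  Sizes are
    scanned from the full hypothesis downward; the first size with a
    match fixes the depth K and breadth m_K of the score.
    """
    if not conformers:
        raise ValueError("need at least one conformer")
    n = hypothesis.n_points
    if not 1 <= min_size <= n:
        raise ValueError(f"min_size must be in [1, {n}]")
    for k in range(n, min_size - 1, -1):
        m_k = 0
        for idx in combinations(range(n), k):
            sub = PharmacophoreHypothesis(tuple(hypothesis.points[i] for i in idx))
            if any(match_subset(sub, c) for c in conformers):
                m_k += 1
        if m_k > 0:
            return (k + m_k / comb(n, k) - 1) / n
    return 0.0


def score_compounds(
    hypothesis: PharmacophoreHypothesis,
    conformers_by_compound: dict[str, list[ConformerFeatures]],
    min_size: int = 3,
) -> dict[str, float]:
    """Continuous score per compound, ready for ranking evaluation."""
    return {
        cid: continuous_score(hypothesis, confs, min_size=min_size)
        for cid, confs in conformers_by_compound.items()
    }


def perturbed_conformer(
    hypothesis: PharmacophoreHypothesis,
    rng: np.random.Generator,
    compound_id: str = "synthetic",
    jitter: float = 0.2,
    drop: int = 0,
) -> ConformerFeatures:
    """Synthetic conformer: rigidly transformed, jittered copy of the hypothesis.

    Test/fixture helper — real conformer features come from upstream
    conformer generation, which is out of scope here.  ``drop`` removes
    that many feature points at random; ``jitter`` is the SD (Angstrom)
    of isotropic positional noise applied before the rigid transform.
    """
    xyz = hypothesis.coords() + rng.normal(0.0, jitter, size=(hypothesis.n_points, 3))
    # random rotation via QR of a Gaussian matrix, then random translation
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    xyz = xyz @ q.T + rng.normal(0.0, 10.0, size=3)
    keep = np.arange(hypothesis.n_points)
    if drop > 0:
        keep = np.sort(rng.choice(keep, size=hypothesis.n_points - drop, replace=False))
    feats = tuple(
        (hypothesis.points[i].feature_type, tuple(float(v) for v in xyz[i])) for i in keep
    )
    return ConformerFeatures(compound_id=compound_id, features=feats)
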