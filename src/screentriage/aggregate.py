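"""Collapsing per-pose and per-stereoisomer scores to per-compound scores.

In-vitro assays report racemic-averaged activity, so in-silico scores
of individual stereoisomers are averaged back to one value per library
compound.  Compounds with up to four undefined stereocenters get every
isomer (at most 2^4 = 16); beyond four, a seed-deterministic random
sample of exactly 16 is used.  Pose ensembles are reduced either by a
Boltzmann-like (softmax-weighted) average, where higher scores mean
stronger predicted binding, or by the best docking pose (the most
favorable free energy, sign-flipped so that higher is better for every
method downstream).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

BOLTZMANN_LIKE = "boltzmann_like"
BEST_POSE = "best_pose"


@dataclass(frozen=True)
class StereoPolicy:
    """How many stereoisomers to enumerate per compound."""

    max_enumerated: int = 16
    enumerate_all_up_to: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_enumerated < 1:
            raise ValueError("max_enumerated must be >= 1")
        if 2 ** self.enumerate_all_up_to != self.max_enumerated:
            raise ValueError(
                "policy inconsistent: 2^enumerate_all_up_to must equal max_enumerated"
            )


@dataclass(frozen=True)
class AggregationPolicy:
    """Pose- and stereoisomer-level reduction rules."""

    pose_rule: str = BOLTZMANN_LIKE
    temperature: float = 1.0
    stereo_rule: str = "mean"

    def __post_init__(self) -> None:
        if self.pose_rule not in (BOLTZMANN_LIKE, BEST_POSE):
            raise ValueError(f"unknown pose_rule {self.pose_rule!r}")
        if self.pose_rule == BOLTZMANN_LIKE and self.temperature <= 0:
            raise ValueError("temperature must be > 0 for boltzmann_like")
        if self.stereo_rule != "mean":
            raise ValueError(f"unknown stereo_rule {self.stereo_rule!r}")


def enumerate_stereoisomers(
    compound_id: str, n_undefined: int, policy: StereoPolicy = StereoPolicy()
) -> list[str]:
    """Stereoisomer identifiers for a compound with n undefined centers.

    Each isomer is named by its R/S assignment bitstring.  For n <=
    ``enumerate_all_up_to`` all 2^n assignments are returned; otherwise
    exactly ``max_enumerated`` distinct assignments are sampled, with a
    per-compound substream derived from the policy seed so the sample is
    reproducible and independent of enumeration order.
    """
    if n_undefined < 0:
        raise ValueError("stereocenter count cannot be negative")
    if n_undefined == 0:
        return [f"{compound_id}_S"]
    if n_undefined <= policy.enumerate_all_up_to:
        codes = range(2 ** n_undefined)
    else:
        rng = np.random.default_rng(
            [policy.seed, zlib.crc32(compound_id.encode()), n_undefined]
        )
        codes = sorted(
            rng.choice(2 ** n_undefined, size=policy.max_enumerated, replace=False)
        )
    return [f"{compound_id}_S{code:0{n_undefined}b}" for code in codes]


def racemic_average(scores) -> float:
    """Arithmetic mean over stereoisomer scores (the racemic expectation)."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("no stereoisomer scores to average")
    return float(arr.mean())


def boltzmann_aggregate(pose_scores, temperature: float = 1.0) -> float:
    """Softmax-weighted mean of pose scores: sum_i s_i exp(s_i/T) / sum_i exp(s_i/T).

    Higher score = stronger predicted binding, so favorable poses
    dominate.  The result always lies in [min, max] of the inputs, tends
    to the arithmetic mean as T -> inf and to the max as T -> 0+, and is
    invariant to adding a constant to every score (computed with
    max-subtraction so large scores cannot overflow).
    """
    s = np.asarray(list(pose_scores), dtype=float)
    if s.size == 0:
        raise ValueError("no pose scores to aggregate")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    z = (s - s.max()) / temperature
    w = np.exp(z)
    w /= w.sum()
    return float(np.dot(s, w))


def docking_ensemble_score(pose_energies) -> float:
    """Best docking pose score under a higher-is-better convention.

    Docking free energies are negative for favorable binding; the most
    favorable (most negative) energy is taken and negated, so a pose set
    {-7.1, -8.3, -6.0} scores 8.3.
    """
    e = np.asarray(list(pose_energies), dtype=float)
    if e.size == 0:
        raise ValueError("no pose energies")
    return float(-e.min())


def aggregate_pose_table(
    poses: pd.DataFrame, policy: AggregationPolicy = AggregationPolicy()
) -> pd.DataFrame:
    """Per-compound scores from a (compound, stereoisomer, pose) score table.

    Expects columns compound_id, stereoisomer_id, pose_id, score.  Poses
    are reduced per stereoisomer by the pose rule, then stereoisomers
    are racemic-averaged; the output has one row per compound.
    """
    required = {"compound_id", "stereoisomer_id", "score"}
    missing = required - set(poses.columns)
    if missing:
        raise ValueError(f"pose table missing columns: {sorted(missing)}")
    if policy.pose_rule == BOLTZMANN_LIKE:
        reduce = lambda s: boltzmann_aggregate(s, policy.temperature)  # noqa: E731
    else:
        reduce = docking_ensemble_score
    per_iso = (
        poses.groupby(["compound_id", "stereoisomer_id"], sort=True)["score"]
        .apply(lambda s: reduce(s.to_numpy()))
        .reset_index(name="iso_score")
    )
    per_cmpd = (
        per_iso.groupby("compound_id", sort=True)["iso_score"]
        .apply(lambda s: racemic_average(s.to_numpy()))
        .reset_index(name="score")
    )
    return per_cmpd
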