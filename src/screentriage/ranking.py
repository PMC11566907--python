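"""Virtual-screening ranking evaluation: hit and scaffold discovery rates.

A ranking orders the library by predicted activity.  Its hit discovery
curve reports, for each library fraction f, the share of all known
hits found among the top ceil(f * N) ranked compounds; random ordering
tracks the diagonal, so anything above it beats unguided screening.
The scaffold discovery curve counts distinct hit clusters with at
least one member in the top fraction, optionally restricted to potency
labels (e.g. nanomolar scaffolds only).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hits import ClusterSet, call_hits

#: Library-fraction grid used in the study's discovery tables.
DEFAULT_FRACTIONS: tuple[float, ...] = (0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0)


class UniverseMismatchError(ValueError):
    """Rankings or hit sets refer to compounds outside the shared universe."""


@dataclass(frozen=True)
class RankingResult:
    """One method's ordered compound scores (descending predicted activity).

    Ties are broken by compound id (ascending) so the order is total and
    reproducible.
    """

    method: str
    entries: tuple[tuple[str, float], ...]

    @classmethod
    def from_scores(cls, method: str, scores: dict[str, float]) -> "RankingResult":
        if len(scores) == 0:
            raise ValueError("empty score table")
        ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(method=method, entries=tuple(ordered))

    @property
    def compound_ids(self) -> list[str]:
        return [cid for cid, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class DiscoveryCurve:
    """Discovery value per library fraction screened for one method."""

    method: str
    points: tuple[tuple[float, float], ...]   # (fraction_screened, value)
    n_hits_total: int
    threshold: float | None = None
    kind: str = "hits"                        # "hits" (fraction) or "scaffolds" (count)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "method": self.method,
                    "threshold": self.threshold,
                    "kind": self.kind,
                    "fraction": f,
                    "value": v,
                }
                for f, v in self.points
            ]
        )

    def value_at(self, fraction: float) -> float:
        for f, v in self.points:
            if math.isclose(f, fraction):
                return v
        raise KeyError(f"fraction {fraction} not on the curve grid")


def top_k(n_total: int, fraction: float, fixed_k: int | None = None) -> int:
    """Number of compounds in the top ``fraction`` (ceil convention)."""
    if fixed_k is not None:
        return min(fixed_k, n_total)
    return min(n_total, math.ceil(fraction * n_total))


def hit_discovery_curve(
    ranking: RankingResult,
    hit_set: set[str],
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    threshold: float | None = None,
) -> DiscoveryCurve:
    """Fraction of hits recovered in each top library fraction."""
    if not hit_set:
        raise ValueError("hit set is empty")
    universe = set(ranking.compound_ids)
    missing = hit_set - universe
    if missing:
        raise UniverseMismatchError(
            f"hits missing from ranking: {sorted(missing)[:5]} (+{max(0, len(missing) - 5)})"
        )
    n = len(ranking)
    is_hit = np.fromiter(
        (cid in hit_set for cid in ranking.compound_ids), dtype=bool, count=n
    )
    cum_hits = np.cumsum(is_hit)
    pts = []
    for f in fractions:
        k = top_k(n, f)
        pts.append((f, float(cum_hits[k - 1] / len(hit_set))))
    return DiscoveryCurve(
        method=ranking.method,
        points=tuple(pts),
        n_hits_total=len(hit_set),
        threshold=threshold,
        kind="hits",
    )


def threshold_sweep(
    ranking: RankingResult,
    records: pd.DataFrame,
    thresholds: list[float],
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
) -> list[DiscoveryCurve]:
    """One hit discovery curve per inhibition threshold (empty sets skipped)."""
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    curves = []
    for t in thresholds:
        hit_set = call_hits(records, threshold=t)
        if not hit_set:
            warnings.warn(f"threshold {t}%: no hits; curve skipped", stacklevel=2)
            continue
        curves.append(hit_discovery_curve(ranking, hit_set, fractions, threshold=t))
    return curves


def scaffold_discovery_curve(
    ranking: RankingResult,
    clusters: ClusterSet,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    label_filter: set[str] | None = None,
) -> DiscoveryCurve:
    """Distinct scaffolds (clusters) with a member in each top fraction.

    ``label_filter`` restricts counting to clusters with those activity
    labels (e.g. {"nanomolar"}); None counts every cluster.
    """
    if label_filter is not None:
        eligible = {k for k, lab in clusters.labels.items() if lab in label_filter}
    else:
        eligible = set(clusters.clusters)
    member_of = clusters.membership()
    n = len(ranking)
    # first rank (1-based) at which each eligible cluster is discovered
    first_rank: dict[int, int] = {}
    for pos, cid in enumerate(ranking.compound_ids, start=1):
        k = member_of.get(cid)
        if k is not None and k in eligible and k not in first_rank:
            first_rank[k] = pos
    pts = []
    for f in fractions:
        cut = top_k(n, f)
        pts.append((f, float(sum(1 for r in first_rank.values() if r <= cut))))
    return DiscoveryCurve(
        method=ranking.method,
        points=tuple(pts),
        n_hits_total=len(eligible),
        kind="scaffolds",
    )


def compare_methods(
    rankings: list[RankingResult],
    hit_set: set[str],
    clusters: ClusterSet | None = None,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Method-by-fraction discovery table plus pairwise fold-ratios.

    All rankings must cover the same compound universe.  A random
    baseline row (expected value = fraction screened) is included.  The
    ratio table reports, per fraction, every ordered method pair's
    ratio of hit discovery values (NaN where the denominator is zero).
    """
    if not rankings:
        raise ValueError("need at least one ranking")
    universe = set(rankings[0].compound_ids)
    for r in rankings[1:]:
        if set(r.compound_ids) != universe:
            diff = universe.symmetric_difference(r.compound_ids)
            raise UniverseMismatchError(
                f"{r.method}: universe differs by {len(diff)} ids, e.g. {sorted(diff)[:5]}"
            )
    rows = []
    curves: dict[str, DiscoveryCurve] = {}
    for r in rankings:
        hc = hit_discovery_curve(r, hit_set, fractions)
        curves[r.method] = hc
        sc = (
            scaffold_discovery_curve(r, clusters, fractions)
            if clusters is not None
            else None
        )
        for i, (f, v) in enumerate(hc.points):
            rows.append(
                {
                    "method": r.method,
                    "fraction": f,
                    "hit_discovery": v,
                    "scaffold_discovery": sc.points[i][1] if sc else np.nan,
                }
            )
    for f in fractions:
        rows.append(
            {
                "method": "random_baseline",
                "fraction": f,
                "hit_discovery": f,
                "scaffold_discovery": np.nan,
            }
        )
    table = pd.DataFrame(rows)

    ratio_rows = []
    methods = [r.method for r in rankings]
    for f in fractions:
        for m1 in methods:
            v1 = curves[m1].value_at(f)
            for m2 in methods:
                if m1 == m2:
                    continue
                v2 = curves[m2].value_at(f)
                ratio_rows.append(
                    {
                        "fraction": f,
                        "method": m1,
                        "versus": m2,
                        "fold_ratio": v1 / v2 if v2 > 0 else np.nan,
                    }
                )
            ratio_rows.append(
                {"fraction": f, "method": m1, "versus": "random_baseline",
                 "fold_ratio": v1 / f if f > 0 else np.nan}
            )
    return table, pd.DataFrame(ratio_rows)
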