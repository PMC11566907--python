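"""Plate-level processing of raw screening fluorescence.

Raw ratio-channel values are normalized per plate against the on-plate
controls so that the negative (DMSO, uninhibited) control mean maps to
0% relative inhibition and the positive (staurosporine, fully
inhibited) control mean maps to 100%.  Plate quality is summarised by
the Z' statistic

    Z' = 1 - 3 (sigma_p + sigma_n) / |mu_p - mu_n|

computed from the control wells; plates below a minimum Z' (0.5 by
convention) are flagged for re-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Expected columns of a raw plate table.
PLATE_COLUMNS = ["plate_id", "well", "role", "compound_id", "raw_value"]

ROLE_SAMPLE = "sample"
ROLE_NEG = "neg"
ROLE_POS = "pos"


class PlateLayoutError(ValueError):
    """A plate is missing a control role or has an inconsistent layout."""


class DegeneratePlateError(ValueError):
    """Control means coincide; normalization is undefined."""


@dataclass(frozen=True)
class PlateStats:
    """Per-plate control statistics and Z' quality-control verdict."""

    plate_id: str
    mu_neg: float
    mu_pos: float
    sigma_neg: float
    sigma_pos: float
    n_neg: int
    n_pos: int
    zprime: float
    passed_qc: bool


def compute_plate_stats(plate: pd.DataFrame, z_min: float = 0.5) -> PlateStats:
    """Control means/SDs (ddof=1) and Z' for a single plate's readings."""
    plate_ids = plate["plate_id"].unique()
    if len(plate_ids) != 1:
        raise PlateLayoutError(f"expected one plate, got ids {list(plate_ids)}")
    neg = plate.loc[plate["role"] == ROLE_NEG, "raw_value"].to_numpy(float)
    pos = plate.loc[plate["role"] == ROLE_POS, "raw_value"].to_numpy(float)
    for name, vals in (("negative", neg), ("positive", pos)):
        if vals.size < 2:
            raise PlateLayoutError(
                f"plate {plate_ids[0]}: need >= 2 {name} control wells, got {vals.size}"
            )
    mu_n, mu_p = float(neg.mean()), float(pos.mean())
    if mu_p == mu_n:
        raise DegeneratePlateError(
            f"plate {plate_ids[0]}: control means coincide ({mu_p})"
        )
    sd_n = float(neg.std(ddof=1))
    sd_p = float(pos.std(ddof=1))
    z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    return PlateStats(
        plate_id=str(plate_ids[0]),
        mu_neg=mu_n,
        mu_pos=mu_p,
        sigma_neg=sd_n,
        sigma_pos=sd_p,
        n_neg=int(neg.size),
        n_pos=int(pos.size),
        zprime=z,
        passed_qc=z >= z_min,
    )


def normalize_plate(plate: pd.DataFrame, stats: PlateStats) -> pd.DataFrame:
    """Append ``k_norm`` (percent relative inhibition) to one plate's rows.

    k_norm = 100 * (k_raw - mu_neg) / (mu_pos - mu_neg).  Values outside
    [0, 100] are preserved; control wells are normalized too (their
    means land at ~0 and ~100 by construction).
    """
    plate_ids = plate["plate_id"].unique()
    if len(plate_ids) != 1 or str(plate_ids[0]) != stats.plate_id:
        raise PlateLayoutError(
            f"stats are for plate {stats.plate_id}, readings for {list(plate_ids)}"
        )
    if stats.mu_pos == stats.mu_neg:
        raise DegeneratePlateError("control means coincide; cannot normalize")
    out = plate.copy()
    out["k_norm"] = (
        100.0 * (out["raw_value"] - stats.mu_neg) / (stats.mu_pos - stats.mu_neg)
    )
    return out


def denormalize(k_norm: np.ndarray | float, stats: PlateStats):
    """Invert normalization (affine); used for round-trip checks."""
    return stats.mu_neg + (np.asarray(k_norm) / 100.0) * (stats.mu_pos - stats.mu_neg)


def normalize_screen(
    readings: pd.DataFrame, z_min: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize every plate and assemble the QC report.

    Returns the normalized readings (all plates, ``k_norm`` appended)
    and a QC table with one row per plate.
    """
    normed, rows = [], []
    for _, plate in readings.groupby("plate_id", sort=True):
        stats = compute_plate_stats(plate, z_min=z_min)
        normed.append(normalize_plate(plate, stats))
        rows.append(
            {
                "plate_id": stats.plate_id,
                "mu_neg": stats.mu_neg,
                "mu_pos": stats.mu_pos,
                "sigma_neg": stats.sigma_neg,
                "sigma_pos": stats.sigma_pos,
                "zprime": stats.zprime,
                "passed": stats.passed_qc,
            }
        )
    return pd.concat(normed, ignore_index=True), pd.DataFrame(rows)


def qc_filter(
    stats: list[PlateStats] | pd.DataFrame, z_min: float = 0.5
) -> tuple[list[str], list[str]]:
    """Partition plate ids into (passed, failed-for-rerun) at Z' >= z_min."""
    if isinstance(stats, pd.DataFrame):
        records = list(zip(stats["plate_id"].astype(str), stats["zprime"]))
    else:
        records = [(s.plate_id, s.zprime) for s in stats]
    passed = [pid for pid, z in records if z >= z_min]
    failed = [pid for pid, z in records if z < z_min]
    return passed, failed


@dataclass(frozen=True)
class ConfirmationResult:
    """Replicate hit-confirmation summary."""

    n_primary: int
    n_confirmed: int
    n_new: int
    precision: float          # percent
    recall: float             # percent
    plate_correlations: dict[str, float] = field(default_factory=dict)


class EmptyHitSetError(ValueError):
    """Precision is undefined for an empty primary hit set."""


def confirmation_metrics(
    primary_hits: set[str],
    replicate_hit_sets: list[set[str]],
    replicate_values: list[pd.DataFrame] | None = None,
) -> ConfirmationResult:
    """Precision/recall of primary hits against replicate re-screens.

    A primary hit is *confirmed* if it appears in every replicate hit
    set; a *new* hit appears in every replicate but not in the primary
    screen.  precision = confirmed / |primary|, recall =
    confirmed / |confirmed U new|, both in percent.  When
    ``replicate_values`` (tables with plate_id, compound_id, k_norm) are
    given, the per-plate Pearson correlation of normalized values
    between consecutive replicate pairs is reported.
    """
    if not primary_hits:
        raise EmptyHitSetError("primary hit set is empty; precision undefined")
    if not replicate_hit_sets:
        raise ValueError("need at least one replicate hit set")
    consensus = set.intersection(*[set(s) for s in replicate_hit_sets])
    confirmed = primary_hits & consensus
    new = consensus - primary_hits
    precision = 100.0 * len(confirmed) / len(primary_hits)
    denom = len(confirmed | new)
    recall = 100.0 * len(confirmed) / denom if denom else float("nan")

    correlations: dict[str, float] = {}
    if replicate_values is not None and len(replicate_values) >= 2:
        for a, b in zip(replicate_values, replicate_values[1:]):
            merged = a.merge(b, on=["plate_id", "compound_id"], suffixes=("_a", "_b"))
            for pid, grp in merged.groupby("plate_id"):
                r = float(np.corrcoef(grp["k_norm_a"], grp["k_norm_b"])[0, 1])
                key = str(pid)
                correlations[key] = min(correlations.get(key, 1.0), r)
    return ConfirmationResult(
        n_primary=len(primary_hits),
        n_confirmed=len(confirmed),
        n_new=len(new),
        precision=precision,
        recall=recall,
        plate_correlations=correlations,
    )
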