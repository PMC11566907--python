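"""Simulation configuration for the synthetic screening campaign.

The defaults describe a 384-well TR-FRET kinase binding screen: DMSO
negative controls in columns 1-2, staurosporine positive controls in
columns 23-24, library compounds single-point in columns 3-22, and an
8-point ~4-fold dose-response dilution series starting at 30 uM run in
triplicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a simulation parameter is out of its valid range."""


#: The study's dose-response dilution grid (uM), ~4-fold steps from 30 uM.
DEFAULT_DOSE_SERIES: tuple[float, ...] = (
    30.0, 7.5, 1.875, 0.469, 0.117, 0.029, 0.007, 0.002,
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic IRAK1-like screening campaign.

    Fluorescence is in arbitrary ratio-channel units; the signal
    *decreases* with inhibition (negative controls sit high, fully
    inhibited positive controls sit low). ``well_sigma`` is additive
    Gaussian read noise per well; with the defaults the expected plate
    Z' is about 0.81, comfortably above the conventional 0.5 QC bound.
    """

    n_compounds: int = 46743
    active_fraction: float = 0.0076
    n_plates: int | None = None          # computed from library size if None
    plate_rows: int = 16
    plate_cols: int = 24
    neg_mu: float = 1000.0               # DMSO control mean (a.u.)
    pos_mu: float = 200.0                # staurosporine control mean (a.u.)
    well_sigma: float = 25.0             # per-well read noise SD (a.u.)
    active_inhibition_mean: float = 85.0   # percent
    active_inhibition_sd: float = 20.0     # percent
    dose_series: tuple[float, ...] = field(default_factory=lambda: DEFAULT_DOSE_SERIES)
    n_replicates: int = 3
    dr_sigma: float = 2.0                # dose-response noise SD (percent)
    score_enrichment: dict[str, float] = field(
        default_factory=lambda: {"hydra_like": 0.8, "docking_like": 0.4, "random": 0.0}
    )
    neg_cols: tuple[int, int] = (1, 2)
    pos_cols: tuple[int, int] = (23, 24)
    sample_cols: tuple[int, int] = (3, 22)   # inclusive range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ConfigurationError("n_compounds must be >= 1")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ConfigurationError("active_fraction must be in [0, 1]")
        # 0 is the documented noiseless limit (used for exactness checks)
        if self.well_sigma < 0:
            raise ConfigurationError("well_sigma must be >= 0")
        if self.plate_rows < 1 or self.plate_cols < 1:
            raise ConfigurationError("plate_rows and plate_cols must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.dr_sigma < 0:
            raise ConfigurationError("dr_sigma must be >= 0")
        ds = tuple(float(x) for x in self.dose_series)
        if not ds:
            raise ConfigurationError("dose_series must be non-empty")
        if any(x <= 0 for x in ds):
            raise ConfigurationError("dose_series concentrations must be positive")
        if any(a <= b for a, b in zip(ds, ds[1:])):
            raise ConfigurationError("dose_series must be strictly decreasing")
        self.dose_series = ds
        for name, e in self.score_enrichment.items():
            if not 0.0 <= e <= 1.0:
                raise ConfigurationError(
                    f"score_enrichment[{name!r}] must be in [0, 1]"
                )

    @property
    def samples_per_plate(self) -> int:
        lo, hi = self.sample_cols
        return self.plate_rows * (hi - lo + 1)

    def required_plates(self) -> int:
        return -(-self.n_compounds // self.samples_per_plate)
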