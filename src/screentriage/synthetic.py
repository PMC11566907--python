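"""Synthetic screening campaign generator.

Emulates the statistical structure of a 384-well kinase-binding HTS:
a combinatorial small-molecule library, single-point primary-screen
plates (32 DMSO negative controls in columns 1-2, 32 staurosporine
positive controls in columns 23-24, samples in columns 3-22), 8-point
~4-fold dose-response dilution series in triplicate, and per-method
virtual-screening scores whose rank enrichment of true actives is
tunable from random (0) to perfectly activity-sorted (1).

Structures come from a fixed set of drug-like core templates decorated
with enumerated substituents, so fingerprints, Tanimoto similarity and
MCS scaffolds behave like they do on real libraries (MCS on random
graphs would be degenerate).  One global seed drives independent
per-stage substreams, so each stage is reproducible in isolation.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors
from scipy.stats import truncnorm

from .config import ConfigurationError, SimulationConfig
from .dose_response import four_pl
from .ranking import RankingResult

# ---------------------------------------------------------------------------
# Structure templates
#
# Each core has two substituent slots {a}/{b} and a light decoration slot
# {d}.  Substituent fragments are written as branch content (first atom
# bonds to the core) and use ring-closure digit 9 so they never collide
# with core ring numbering.

CORES: tuple[str, ...] = (
    "O=C(Nc1ccc({a})c({d})c1)c1ccc({b})cn1",
    "c1cc({a})cc({d})c1-c1nc({b})cs1",
    "O=S(=O)(c1ccc({a})cc1)Nc1ccc({b})c({d})n1",
    "Cn1c({a})nc2cc({b})c({d})cc21",
    "O=C(c1cc({d})cc({a})c1)N1CCN({b})CC1",
    "c1cc({d})c2nc({a})nc({b})c2c1",
    "O=C(Nc1ccc({a})cc1)Nc1cc({b})cc({d})c1",
    "c1cc({a})c({d})cc1C(=O)N1CCC({b})CC1",
    "c1nn(C)c({a})c1C(=O)Nc1ccc({b})c({d})c1",
    "c1oc({a})nc1-c1ccc({b})c({d})c1",
    "N#Cc1cc({a})c({d})cc1NC({b})=O",
    "O=C(O)c1cc({a})c2cc({b})c({d})cc2c1",
)

#: Substituents; undefined-stereocenter content ranges 0-3 per fragment,
#: so two slots span 0-6 per compound.
SUBSTITUENTS: tuple[str, ...] = (
    # no stereocenters
    "[H]", "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "F", "Cl", "Br", "O",
    "OC", "OCC", "N", "NC", "N(C)C", "C#N", "[N+](=O)[O-]", "C(F)(F)F",
    "S(C)(=O)=O", "C(=O)O", "C(=O)NC", "CO", "CN", "CCO", "CCN",
    "OC(F)F", "SC", "c9ccccc9", "c9ccncc9", "C(=O)C",
    # one stereocenter
    "C(C)O", "C(C)N", "C(C)F", "C(C)CC", "C(O)CC", "C(N)CC", "CC(O)CC",
    "C(C)C(=O)O",
    # two stereocenters
    "C(C)C(C)O", "C(O)C(N)C", "C(F)C(C)O", "C(C)C(N)CC", "C(O)C(O)C",
    # three stereocenters
    "C(O)C(N)C(F)C", "C(C)C(O)C(N)C",
)

DECORATIONS: tuple[str, ...] = ("[H]", "C", "F", "Cl", "OC")


def _assemble(core_i: int, a_i: int, b_i: int, d_i: int) -> str:
    return CORES[core_i].format(
        a=SUBSTITUENTS[a_i], b=SUBSTITUENTS[b_i], d=DECORATIONS[d_i]
    )


def template_space_size() -> int:
    return len(CORES) * len(SUBSTITUENTS) ** 2 * len(DECORATIONS)


def _decode(idx: int) -> tuple[int, int, int, int]:
    ns, nd = len(SUBSTITUENTS), len(DECORATIONS)
    d_i = idx % nd
    idx //= nd
    b_i = idx % ns
    idx //= ns
    a_i = idx % ns
    core_i = idx // ns
    return core_i, a_i, b_i, d_i


def generate_library(config: SimulationConfig) -> pd.DataFrame:
    """Generate the compound library table.

    Returns a frame with columns compound_id, smiles (canonical,
    salt-free by construction), mw and n_undefined_stereocenters.
    Deterministic for a fixed config seed; duplicate structures arising
    from different template combinations are dropped and resampled.
    """
    total = template_space_size()
    if config.n_compounds > total:
        raise ConfigurationError(
            f"n_compounds={config.n_compounds} exceeds the template space ({total})"
        )
    rng = np.random.default_rng([config.seed, 1])
    order = rng.permutation(total)
    seen: set[str] = set()
    rows = []
    for idx in order:
        core_i, a_i, b_i, d_i = _decode(int(idx))
        mol = Chem.MolFromSmiles(_assemble(core_i, a_i, b_i, d_i))
        if mol is None:  # pragma: no cover - templates are validated by tests
            continue
        smi = Chem.MolToSmiles(mol)
        if smi in seen:
            continue
        seen.add(smi)
        rows.append(
            {
                "smiles": smi,
                "mw": float(Descriptors.MolWt(mol)),
                "n_undefined_stereocenters": int(
                    rdMolDescriptors.CalcNumUnspecifiedAtomStereoCenters(mol)
                ),
            }
        )
        if len(rows) == config.n_compounds:
            break
    if len(rows) < config.n_compounds:
        raise ConfigurationError(
            f"template space yielded only {len(rows)} unique structures"
        )
    lib = pd.DataFrame(rows)
    lib.insert(0, "compound_id", [f"CMPD{i:06d}" for i in range(len(lib))])
    return lib


# ---------------------------------------------------------------------------
# Primary screen


class CapacityError(ValueError):
    """Library exceeds the sample-well capacity of the requested plates."""


def _well_name(row: int, col: int) -> str:
    return f"{chr(ord('A') + row)}{col:02d}"


def simulate_primary_screen(
    library: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate single-point primary-screen plates for the whole library.

    Returns ``(readings, truth)``.  ``readings`` has one row per
    occupied well (plate_id, well, role, compound_id, raw_value);
    control wells carry an empty compound_id.  ``truth`` records the
    simulated ground truth per compound (is_active, true_inhibition in
    percent).  Sample raw value is
    ``neg_mu + (pos_mu - neg_mu) * inhibition/100 + N(0, well_sigma)``;
    actives (probability ``active_fraction``) draw inhibition from a
    normal truncated to [0, 120], inactives from a zero-centred normal
    whose SD matches the well noise expressed in percent.
    """
    if library.empty:
        raise ConfigurationError("library is empty")
    n = len(library)
    per_plate = config.samples_per_plate
    n_plates = config.n_plates if config.n_plates is not None else config.required_plates()
    if n > n_plates * per_plate:
        raise CapacityError(
            f"{n} compounds exceed {n_plates} plates x {per_plate} sample wells; "
            f"need {config.required_plates()} plates"
        )
    rng = np.random.default_rng([config.seed, 2])

    is_active = rng.random(n) < config.active_fraction
    span = abs(config.pos_mu - config.neg_mu)
    pct_sigma = 100.0 * config.well_sigma / span
    inhibition = rng.normal(0.0, pct_sigma, size=n) if pct_sigma > 0 else np.zeros(n)
    n_act = int(is_active.sum())
    if n_act:
        m, sd = config.active_inhibition_mean, config.active_inhibition_sd
        inhibition[is_active] = truncnorm.rvs(
            (0.0 - m) / sd, (120.0 - m) / sd, loc=m, scale=sd,
            size=n_act, random_state=rng,
        )
    truth = pd.DataFrame(
        {
            "compound_id": library["compound_id"].astype(str).to_numpy(),
            "is_active": is_active,
            "true_inhibition": inhibition,
        }
    )

    lo, hi = config.sample_cols
    ids = truth["compound_id"].to_numpy()
    rows = []
    k = 0
    for p in range(n_plates):
        plate_id = f"P{p + 1:03d}"
        for col in config.neg_cols:
            for r in range(config.plate_rows):
                rows.append((plate_id, _well_name(r, col), "neg", "", config.neg_mu))
        for col in range(lo, hi + 1):
            for r in range(config.plate_rows):
                if k >= n:
                    break
                signal = config.neg_mu + (config.pos_mu - config.neg_mu) * (
                    inhibition[k] / 100.0
                )
                rows.append((plate_id, _well_name(r, col), "sample", ids[k], signal))
                k += 1
        for col in config.pos_cols:
            for r in range(config.plate_rows):
                rows.append((plate_id, _well_name(r, col), "pos", "", config.pos_mu))
        if k >= n and p + 1 == n_plates:
            break
    readings = pd.DataFrame(
        rows, columns=["plate_id", "well", "role", "compound_id", "raw_value"]
    )
    if config.well_sigma > 0:
        readings["raw_value"] = readings["raw_value"] + rng.normal(
            0.0, config.well_sigma, size=len(readings)
        )
    return readings, truth


# ---------------------------------------------------------------------------
# Dose response


def true_fits_from_truth(
    truth: pd.DataFrame, config: SimulationConfig, compound_ids: list[str] | None = None
) -> pd.DataFrame:
    """Ground-truth 4PL parameters for (a subset of) screened compounds.

    Actives get a full sigmoid: top asymptote A near their single-point
    inhibition, baseline D = 0, Hill slope ~U(0.8, 1.5) and inflection C
    log-uniform in [0.01, 10] uM.  Inactives get an essentially flat
    curve with C far above the tested range.
    """
    rng = np.random.default_rng([config.seed, 5])
    t = truth if compound_ids is None else truth[
        truth["compound_id"].isin(compound_ids)
    ].reset_index(drop=True)
    nrows = len(t)
    B = rng.uniform(0.8, 1.5, size=nrows)
    C = 10.0 ** rng.uniform(-2.0, 1.0, size=nrows)
    A = np.clip(t["true_inhibition"].to_numpy(), 0.0, 110.0)
    active = t["is_active"].to_numpy()
    C = np.where(active, C, 1e4)          # inactive: inflection far out of range
    A = np.where(active, A, np.maximum(A, 5.0))
    return pd.DataFrame(
        {
            "compound_id": t["compound_id"].astype(str).to_numpy(),
            "A": A, "B": B, "C": C, "D": 0.0,
        }
    )


def simulate_dose_response(
    true_fits: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Triplicate 8-point dose-response measurements from true 4PL curves.

    One row per (compound, concentration, replicate); the response is
    the 4PL value at the true parameters plus N(0, dr_sigma) noise.
    """
    doses = np.asarray(config.dose_series, dtype=float)
    if np.any(doses <= 0):
        raise ConfigurationError("dose_series concentrations must be positive")
    rng = np.random.default_rng([config.seed, 3])
    frames = []
    for row in true_fits.itertuples():
        clean = four_pl(doses, row.A, row.B, row.C, row.D)
        for rep in range(1, config.n_replicates + 1):
            noise = (
                rng.normal(0.0, config.dr_sigma, size=len(doses))
                if config.dr_sigma > 0
                else 0.0
            )
            frames.append(
                pd.DataFrame(
                    {
                        "compound_id": row.compound_id,
                        "conc_uM": doses,
                        "replicate": rep,
                        "response": clean + noise,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Virtual-screening method scores


def simulate_method_scores(
    truth: pd.DataFrame,
    config: SimulationConfig,
    methods: list[str] | None = None,
) -> list[RankingResult]:
    """Per-method compound scores with tunable rank enrichment of actives.

    score = enrichment * (true inhibition / 120, clipped to [0, 1])
          + (1 - enrichment) * Uniform(0, 1).
    Enrichment 0 gives exchangeable (random) ranks; enrichment 1 sorts
    exactly by true activity.
    """
    if methods is None:
        methods = list(config.score_enrichment)
    unknown = [m for m in methods if m not in config.score_enrichment]
    if unknown:
        raise ConfigurationError(
            f"unknown method(s) {unknown}; configured: {list(config.score_enrichment)}"
        )
    ids = truth["compound_id"].astype(str).to_numpy()
    act = np.clip(truth["true_inhibition"].to_numpy(), 0.0, 120.0) / 120.0
    results = []
    for j, method in enumerate(methods):
        e = config.score_enrichment[method]
        rng = np.random.default_rng([config.seed, 4, j])
        noise = rng.random(len(ids))
        scores = e * act + (1.0 - e) * noise
        results.append(RankingResult.from_scores(method, dict(zip(ids, scores))))
    return results


# ---------------------------------------------------------------------------
# CSV export


def write_simulation(
    outdir,
    library: pd.DataFrame,
    readings: pd.DataFrame,
    truth: pd.DataFrame,
    scores: list[RankingResult] | None = None,
    dose_response: pd.DataFrame | None = None,
) -> None:
    """Write the generated campaign as the pipeline's CSV input files."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    library.to_csv(out / "library.csv", index=False)
    readings.to_csv(out / "plates.csv", index=False)
    truth.to_csv(out / "ground_truth.csv", index=False)
    if scores is not None:
        pd.concat(
            [
                pd.DataFrame(
                    {"method": r.method,
                     "compound_id": [c for c, _ in r.entries],
                     "score": [s for _, s in r.entries]}
                )
                for r in scores
            ],
            ignore_index=True,
        ).to_csv(out / "scores.csv", index=False)
    if dose_response is not None:
        dose_response.to_csv(out / "dose_response.csv", index=False)


def validate_templates() -> list[str]:
    """Sanity check: every core x first-substituent combination parses."""
    bad = []
    for core_i in range(len(CORES)):
        for a_i, b_i, d_i in itertools.product(
            range(len(SUBSTITUENTS)), [0], range(len(DECORATIONS))
        ):
            smi = _assemble(core_i, a_i, b_i, d_i)
            if Chem.MolFromSmiles(smi) is None:
                bad.append(smi)
    return bad
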