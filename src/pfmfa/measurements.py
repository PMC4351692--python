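"""Mass-spectrometric measurement panel: specs, noise, covariance, exclusion.

Observed quantities are carbon-backbone mass-isotopomer fractions of
metabolite fragments (LC-MS/MS) or of amino acids read through their
biosynthetic precursor pools (GC-MS/MS).  Derivatisation and adduct atoms
are assumed corrected upstream, so a measurement maps directly onto one EMU
of the network model.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .labeling import EMU, EmuKey, make_emu
from .network import NetworkModel

STD_FLOOR = 0.01  # absolute minimum standard deviation on the fraction scale


@dataclass(frozen=True)
class MeasurementSpec:
    """One measured fragment: compound, model pool, carbon subset, noise level."""

    compound: str
    pool: str
    positions: tuple[int, ...]
    instrument: str  # "LC" or "GC"
    rsd: float
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.rsd <= 0:
            raise ValueError(f"{self.compound}: relative STD must be positive")
        if self.replicates < 1:
            raise ValueError(f"{self.compound}: need at least one replicate")

    @property
    def n_masses(self) -> int:
        return len(self.positions) + 1

    def emu(self, model: NetworkModel) -> EMU:
        return make_emu(model, self.pool, self.positions)

    @property
    def key(self) -> EmuKey:
        return (self.pool, tuple(sorted(self.positions)))


@dataclass
class RateSet:
    """Extracellular rates with standard deviations.

    Uptake and biomass production are in mmolC/(gDW h), CO2 excretion in
    mmol/(gDW h), growth rate in 1/h.  Alginate production is zero for both
    strains studied here but kept for bookkeeping.
    """

    uptake_c: tuple[float, float]
    biomass_c: tuple[float, float]
    co2: tuple[float, float]
    growth_rate: tuple[float, float]
    alginate_c: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("uptake_c", "biomass_c", "co2", "growth_rate", "alginate_c"):
            value, std = getattr(self, name)
            if value < 0:
                raise ValueError(f"negative rate {name}")
            if std <= 0:
                raise ValueError(f"non-positive STD for {name}")


class MeasurementSet:
    """Replicate MID measurements for a panel, with exclusion bookkeeping."""

    def __init__(
        self,
        specs: Sequence[MeasurementSpec],
        replicates: Mapping[int, np.ndarray],
        rates: RateSet | None = None,
        strict: bool = True,
    ) -> None:
        if not specs:
            raise ValueError("empty measurement set")
        self.specs = list(specs)
        self.replicates: dict[int, np.ndarray] = {}
        for i, spec in enumerate(self.specs):
            reps = np.asarray(replicates[i], dtype=float)
            if reps.shape != (spec.replicates, spec.n_masses):
                raise ValueError(
                    f"{spec.compound}: replicate array shape {reps.shape} does not "
                    f"match spec ({spec.replicates} x {spec.n_masses})"
                )
            if strict:
                sums = reps.sum(axis=1)
                if np.any(np.abs(sums - 1.0) > 1e-6):
                    raise ValueError(f"{spec.compound}: replicate MID does not sum to 1")
            self.replicates[i] = reps
        self.rates = rates
        self.included: dict[int, np.ndarray] = {
            i: np.ones(spec.n_masses, dtype=bool) for i, spec in enumerate(self.specs)
        }
        self.exclusion_log: list[dict] = []
        self._exclusion_applied = False

    # -- summaries ---------------------------------------------------------
    def mean(self, i: int) -> np.ndarray:
        return self.replicates[i].mean(axis=0)

    def stds(self, i: int, floor: float = STD_FLOOR) -> np.ndarray:
        """Per-fraction STD: instrument RSD times the replicate mean, floored.

        The panel-wide relative STD (an average over replicates, per
        instrument and condition) is the noise model; the floor accounts
        for measurements close to the detection limit and is interpreted
        as an absolute 0.01 on the fraction scale.
        """
        return np.maximum(self.specs[i].rsd * self.mean(i), floor)

    def n_included(self) -> int:
        return int(sum(mask.sum() for mask in self.included.values()))

    def flat(self, floor: float = STD_FLOOR):
        """Included (mean, std) pairs flattened in panel order."""
        means, stds, index = [], [], []
        for i, spec in enumerate(self.specs):
            mask = self.included[i]
            means.append(self.mean(i)[mask])
            stds.append(self.stds(i, floor)[mask])
            for m in np.nonzero(mask)[0]:
                index.append((i, int(m)))
        return np.concatenate(means), np.concatenate(stds), index

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, spec in enumerate(self.specs):
            frag = ",".join(map(str, spec.positions))
            for r, mid in enumerate(self.replicates[i]):
                for shift, frac in enumerate(mid):
                    rows.append(
                        {
                            "compound": spec.compound,
                            "pool": spec.pool,
                            "instrument": spec.instrument,
                            "fragment": frag,
                            "mass_shift": shift,
                            "replicate": r,
                            "fraction": frac,
                            "included": bool(self.included[i][shift]),
                        }
                    )
        return pd.DataFrame(rows)


def measurement_set_from_frame(
    df: pd.DataFrame,
    specs: Sequence[MeasurementSpec],
    rates: RateSet | None = None,
) -> MeasurementSet:
    """Rebuild a MeasurementSet from its tidy-table export.

    Rows are matched to specs by (compound, fragment) columns; the table
    must contain every replicate and mass shift the specs declare.
    """
    reps: dict[int, np.ndarray] = {}
    for i, spec in enumerate(specs):
        frag = ",".join(map(str, spec.positions))
        sub = df[(df["compound"] == spec.compound) & (df["fragment"] == frag)]
        if sub.empty:
            raise ValueError(f"no rows for {spec.compound} fragment {frag}")
        arr = np.zeros((spec.replicates, spec.n_masses))
        for _, row in sub.iterrows():
            arr[int(row["replicate"]), int(row["mass_shift"])] = row["fraction"]
        reps[i] = arr
    return MeasurementSet(specs, reps, rates=rates)


def build_measurement_covariance(
    measurement_set: MeasurementSet,
    floor: float = STD_FLOOR,
    relative_floor: bool = False,
) -> np.ndarray:
    """Diagonal covariance over the included mass-isotopomer fractions.

    The STD floor defaults to an absolute 0.01 on the fraction scale; set
    ``relative_floor`` to floor the relative STD instead.
    """
    means, stds, _ = measurement_set.flat(floor=0.0)
    if relative_floor:
        stds = np.maximum(stds, floor * means)
    else:
        stds = np.maximum(stds, floor)
    return np.diag(stds**2)


def simulate_measurements(
    true_mids: Mapping[EmuKey, np.ndarray],
    specs: Sequence[MeasurementSpec],
    rng_seed: int,
    noise_scale: float = 1.0,
    noise_model: str = "multiplicative",
    rates: RateSet | None = None,
) -> MeasurementSet:
    """Draw replicate MID measurements around simulated true values.

    ``multiplicative`` noise (the default, matching how relative STDs are
    quoted) perturbs each fraction by Gaussian noise proportional to it,
    clips negatives and renormalises.  ``gaussian`` applies additive noise
    at the floored STD without renormalisation — a correctly-specified
    counterpart for statistical calibration studies.
    """
    rng = np.random.default_rng(rng_seed)
    reps: dict[int, np.ndarray] = {}
    for i, spec in enumerate(specs):
        if spec.key not in true_mids:
            raise KeyError(f"no simulated MID for {spec.compound} ({spec.key})")
        truth = np.asarray(true_mids[spec.key], dtype=float)
        out = np.empty((spec.replicates, spec.n_masses))
        for r in range(spec.replicates):
            z = rng.standard_normal(spec.n_masses)
            if noise_model == "multiplicative":
                noisy = truth * (1.0 + noise_scale * spec.rsd * z)
                noisy = np.clip(noisy, 0.0, None)
                total = noisy.sum()
                noisy = truth.copy() if total == 0 else noisy / total
            elif noise_model == "gaussian":
                std = np.maximum(spec.rsd * truth, STD_FLOOR)
                noisy = truth + noise_scale * std * z
            else:
                raise ValueError(f"unknown noise model {noise_model!r}")
            out[r] = noisy
        reps[i] = out
    # additive-Gaussian draws are intentionally not renormalised (that would
    # distort the assumed diagonal covariance), so sum checks are relaxed
    return MeasurementSet(specs, reps, rates=rates, strict=noise_model == "multiplicative")


def exclude_discrepant(
    measurement_set: MeasurementSet,
    simulated_mids: Mapping[EmuKey, np.ndarray],
    abundance_threshold: float = 0.01,
    residual_threshold: float = 5.0,
    floor: float = STD_FLOOR,
) -> MeasurementSet:
    """Exclude low-abundance fractions with extraordinary discrepancies.

    A fraction is dropped only when its replicate-mean abundance is below
    ``abundance_threshold`` AND its standardised residual against the
    best-fit simulation exceeds ``residual_threshold``.  Applied at most
    once (a single re-fit pass); every exclusion is logged with both
    numbers.
    """
    if abundance_threshold <= 0 or residual_threshold <= 0:
        raise ValueError("exclusion thresholds must be positive")
    if measurement_set._exclusion_applied:
        return measurement_set
    for i, spec in enumerate(measurement_set.specs):
        sim = np.asarray(simulated_mids[spec.key], dtype=float)
        mean = measurement_set.mean(i)
        stds = measurement_set.stds(i, floor)
        resid = (mean - sim) / stds
        for m in range(spec.n_masses):
            if mean[m] < abundance_threshold and abs(resid[m]) > residual_threshold:
                measurement_set.included[i][m] = False
                measurement_set.exclusion_log.append(
                    {
                        "compound": spec.compound,
                        "fragment": ",".join(map(str, spec.positions)),
                        "mass_shift": m,
                        "abundance": float(mean[m]),
                        "standardised_residual": float(resid[m]),
                    }
                )
    measurement_set._exclusion_applied = True
    return measurement_set
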