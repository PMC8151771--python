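"""Synthetic olive-drupe datasets: reference chemistry plus NIR spectra.

The generator emulates the measurement campaign the pipeline is built for:
267 olive sample units, each analysed in duplicate for five quality
parameters (moisture, oil, soluble solids, total phenolic content, DPPH
antioxidant activity), and scanned in duplicate by three acquisition
systems — an FT-NIR spectrometer with an integrating sphere and with a
fiber-optic probe (12,500-3,600 cm^-1) and a handheld Vis/NIR device
(500-1,000 nm).

Spectra follow a Beer-Lambert mixing model: each constituent contributes a
fixed set of Gaussian absorption bands scaled by its concentration, and
each replicate scan is corrupted by a multiplicative scatter factor, an
additive (offset + tilt) baseline, and i.i.d. detector noise — exactly the
artifact classes that SNV and the Savitzky-Golay first derivative are
meant to remove.

Randomness contract: a single root seed drives everything through named
sub-streams (chemistry first, then one stream per instrument in the order
the grids are configured), so identical configurations are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import RESPONSES, ChemTable, ConfigurationError, SpectraBlock

# Constituent ranges observed across cultivars/ripening stages (native units).
# Soluble solids span is a plausible default for olive pulp (not tabulated in
# the study data the generator emulates; flagged as invented).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "moisture_pct": (39.3, 87.2),
    "oil_pct": (1.9, 26.0),
    "ssc_brix": (5.0, 30.0),  # invented default
    "tpc_ga_kg": (2.5, 60.6),
    "dpph_inhib_mg": (2.4, 165.0),
}


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: center and sigma in axis units,
    amplitude in absorbance per native concentration unit."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not (self.width > 0):
            raise ConfigurationError(f"band width must be > 0, got {self.width}")
        if not math.isfinite(self.amplitude):
            raise ConfigurationError("band amplitude must be finite")


# Default band libraries keyed by axis unit.  FT-NIR assignments follow the
# usual overtone/combination attributions for water (6900, 5200 cm^-1 broad
# bands), oil C-H overtones (8300, 5800/5650, 4335/4262 cm^-1) and the
# phenol-correlated 8700-8300 / 5800-5650 cm^-1 regions; Vis/NIR uses the
# anthocyanin (~540 nm) and chlorophyll (~680 nm) pigment peaks plus the
# third-overtone water/C-H bands around 750-970 nm.  Sugar (soluble-solids)
# bands are invented but placed in chemically plausible C-H/O-H regions.
DEFAULT_BANDS: dict[str, dict[str, tuple[BandSpec, ...]]] = {
    "cm-1": {
        "moisture_pct": (
            BandSpec(6900.0, 330.0, 0.010),
            BandSpec(5200.0, 230.0, 0.012),
        ),
        "oil_pct": (
            BandSpec(8300.0, 80.0, 0.008),
            BandSpec(5800.0, 45.0, 0.020),
            BandSpec(5650.0, 45.0, 0.016),
            BandSpec(4335.0, 25.0, 0.024),
            BandSpec(4262.0, 25.0, 0.022),
        ),
        "ssc_brix": (
            BandSpec(4390.0, 60.0, 0.012),
            BandSpec(6300.0, 120.0, 0.006),
        ),
        "tpc_ga_kg": (
            BandSpec(8500.0, 120.0, 0.004),
            BandSpec(5725.0, 50.0, 0.006),
        ),
        "dpph_inhib_mg": (
            BandSpec(8450.0, 110.0, 0.0012),
            BandSpec(5690.0, 45.0, 0.0015),
        ),
    },
    "nm": {
        "moisture_pct": (
            BandSpec(970.0, 18.0, 0.009),
            BandSpec(750.0, 12.0, 0.004),
        ),
        "oil_pct": (
            BandSpec(930.0, 12.0, 0.012),
            BandSpec(850.0, 12.0, 0.008),
        ),
        "ssc_brix": (
            BandSpec(910.0, 15.0, 0.008),
            BandSpec(740.0, 10.0, 0.004),
        ),
        "tpc_ga_kg": (
            BandSpec(540.0, 25.0, 0.006),
            BandSpec(680.0, 12.0, 0.005),
        ),
        "dpph_inhib_mg": (
            BandSpec(560.0, 30.0, 0.0015),
            BandSpec(680.0, 15.0, 0.0012),
        ),
    },
}


@dataclass(frozen=True)
class InstrumentGrid:
    """Digitization grid of one acquisition system.

    ``gain`` is a global reflectance-geometry factor (the fiber-optic probe
    reads systematically higher absorbances than the integrating sphere).
    """

    name: str
    axis_unit: str
    start: float
    stop: float
    n_points: int
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.axis_unit not in ("cm-1", "nm"):
            raise ConfigurationError(f"unknown axis unit {self.axis_unit!r}")
        if self.n_points < 2 or not (self.stop > self.start):
            raise ConfigurationError("grid needs stop > start and >= 2 points")

    def axis(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_points)


# Default grids.  FT-NIR point counts are chosen so the standard trim to
# 4,000-10,500 cm^-1 leaves 1,686 variables per block; the portable device
# is used over its whole 500-1,000 nm range (1,647 variables, ~0.3 nm step).
DEFAULT_GRIDS: tuple[InstrumentGrid, ...] = (
    InstrumentGrid("sphere", "cm-1", 3600.0, 12500.0, 2309, gain=1.0),
    InstrumentGrid("probe", "cm-1", 3600.0, 12500.0, 2309, gain=1.3),
    InstrumentGrid("portable", "nm", 500.0, 1000.0, 1647, gain=1.0),
)


@dataclass
class GeneratorConfig:
    """Everything that defines one synthetic campaign.

    Noise magnitudes are in absorbance units (scatter_sd is the relative sd
    of the multiplicative factor); ``replicate_chem_cv`` is the coefficient
    of variation of a single laboratory replicate.
    """

    n_units: int = 267
    n_replicates_spectra: int = 2
    n_replicates_chem: int = 2
    seed: int = 0
    constituent_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    grids: tuple[InstrumentGrid, ...] = DEFAULT_GRIDS
    band_library: dict[str, dict[str, tuple[BandSpec, ...]]] = field(
        default_factory=lambda: {u: dict(v) for u, v in DEFAULT_BANDS.items()}
    )
    marginal: str = "uniform"  # or "truncnorm"
    moisture_oil_corr: float = -0.5  # latent (Gaussian copula) correlation
    tpc_dpph_rank_corr: float = 0.6  # target Spearman correlation
    scatter_sd: float = 0.08
    baseline_sd: float = 0.02
    noise_sd: float = 0.002
    replicate_chem_cv: float = 0.03

    def __post_init__(self) -> None:
        if self.n_units < 4:
            raise ConfigurationError("n_units must be >= 4")
        if self.n_replicates_spectra < 1 or self.n_replicates_chem < 1:
            raise ConfigurationError("replicate counts must be >= 1")
        for name in RESPONSES:
            if name not in self.constituent_ranges:
                raise ConfigurationError(f"missing constituent range for {name!r}")
            lo, hi = self.constituent_ranges[name]
            if not (lo < hi):
                raise ConfigurationError(
                    f"invalid range for {name!r}: ({lo}, {hi}) needs min < max"
                )
        for sd_name in ("scatter_sd", "baseline_sd", "noise_sd", "replicate_chem_cv"):
            if getattr(self, sd_name) < 0:
                raise ConfigurationError(f"{sd_name} must be >= 0")
        if self.marginal not in ("uniform", "truncnorm"):
            raise ConfigurationError(f"unknown marginal {self.marginal!r}")
        if not -1.0 < self.moisture_oil_corr < 1.0:
            raise ConfigurationError("moisture_oil_corr must be in (-1, 1)")
        if not -1.0 < self.tpc_dpph_rank_corr < 1.0:
            raise ConfigurationError("tpc_dpph_rank_corr must be in (-1, 1)")
        names = [g.name for g in self.grids]
        if len(set(names)) != len(names):
            raise ConfigurationError("instrument grid names must be unique")

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["grids"] = [asdict(g) for g in self.grids]
        d["band_library"] = {
            unit: {c: [asdict(b) for b in bands] for c, bands in lib.items()}
            for unit, lib in self.band_library.items()
        }
        d["constituent_ranges"] = {
            k: list(v) for k, v in self.constituent_ranges.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown generator config keys: {sorted(unknown)}")
        d = dict(d)
        if "grids" in d:
            d["grids"] = tuple(InstrumentGrid(**g) for g in d["grids"])
        if "band_library" in d:
            d["band_library"] = {
                unit: {c: tuple(BandSpec(**b) for b in bands) for c, bands in lib.items()}
                for unit, lib in d["band_library"].items()
            }
        if "constituent_ranges" in d:
            d["constituent_ranges"] = {
                k: (float(v[0]), float(v[1])) for k, v in d["constituent_ranges"].items()
            }
        return cls(**d)


def _unit_labels(n: int) -> np.ndarray:
    width = max(3, len(str(n)))
    return np.array([f"U{i + 1:0{width}d}" for i in range(n)])


def _latent_correlation(config: GeneratorConfig) -> np.ndarray:
    """Correlation of the latent Gaussian copula over the five responses.

    The TPC-DPPH entry is back-solved from the target Spearman coefficient
    via rho = 2 sin(pi * r_s / 6), exact for bivariate Gaussian copulas.
    """
    rho = np.eye(len(RESPONSES))
    i_m, i_o = RESPONSES.index("moisture_pct"), RESPONSES.index("oil_pct")
    i_t, i_d = RESPONSES.index("tpc_ga_kg"), RESPONSES.index("dpph_inhib_mg")
    rho[i_m, i_o] = rho[i_o, i_m] = config.moisture_oil_corr
    r_td = 2.0 * math.sin(math.pi * config.tpc_dpph_rank_corr / 6.0)
    rho[i_t, i_d] = rho[i_d, i_t] = r_td
    return rho


def draw_chemistry(config: GeneratorConfig) -> ChemTable:
    """Draw per-unit true concentrations and duplicate lab measurements.

    True values come from a Gaussian copula (moisture and oil negatively
    correlated; DPPH a noisy monotone function of TPC) with uniform or
    range-truncated-normal marginals on the configured constituent ranges.
    Each laboratory replicate is the true value perturbed by multiplicative
    noise of coefficient of variation ``replicate_chem_cv``.

    Returns a :class:`ChemTable` whose ``data`` has one row per
    (unit, replicate); the noiseless truth is attached as ``table.truth``
    (a DataFrame indexed by unit_id).
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_units
    rho = _latent_correlation(config)
    chol = np.linalg.cholesky(rho)
    z = rng.standard_normal((n, len(RESPONSES))) @ chol.T
    u = stats.norm.cdf(z)

    truth = {}
    for j, name in enumerate(RESPONSES):
        lo, hi = config.constituent_ranges[name]
        if config.marginal == "uniform":
            truth[name] = lo + u[:, j] * (hi - lo)
        else:  # truncated normal centered on the range, sd = span/4
            mu, sd = 0.5 * (lo + hi), (hi - lo) / 4.0
            a, b = (lo - mu) / sd, (hi - mu) / sd
            truth[name] = stats.truncnorm.ppf(u[:, j], a, b, loc=mu, scale=sd)
    truth_df = pd.DataFrame(truth, index=pd.Index(_unit_labels(n), name="unit_id"))

    rows = []
    for rep in range(1, config.n_replicates_chem + 1):
        noise = rng.standard_normal((n, len(RESPONSES)))
        values = truth_df.to_numpy() * (1.0 + config.replicate_chem_cv * noise)
        df = pd.DataFrame(values, columns=RESPONSES)
        df.insert(0, "replicate", rep)
        df.insert(0, "unit_id", truth_df.index.to_numpy())
        rows.append(df)
    data = pd.concat(rows, ignore_index=True)
    data = data.sort_values(["unit_id", "replicate"], kind="stable").reset_index(
        drop=True
    )
    table = ChemTable(data=data)
    table.truth = truth_df  # ground truth rides along for recovery tests
    return table


def clean_spectra(
    truth: pd.DataFrame, grid: InstrumentGrid, config: GeneratorConfig
) -> np.ndarray:
    """Noise-free Beer-Lambert mixing: rows = units, columns = grid points."""
    try:
        library = config.band_library[grid.axis_unit]
    except KeyError as exc:
        raise ConfigurationError(
            f"no band library for axis unit {grid.axis_unit!r}"
        ) from exc
    axis = grid.axis()
    # design matrix: absorptivity of each constituent at each axis point
    eps = np.zeros((len(RESPONSES), axis.size))
    for j, name in enumerate(RESPONSES):
        for band in library.get(name, ()):
            eps[j] += band.amplitude * np.exp(
                -0.5 * ((axis - band.center) / band.width) ** 2
            )
    conc = truth[RESPONSES].to_numpy()
    return grid.gain * conc @ eps


def render_spectra(
    chem: ChemTable, grid: InstrumentGrid, config: GeneratorConfig
) -> SpectraBlock:
    """Render replicate spectra for one instrument.

    Each replicate scan r of unit i is

        A_ir = m_ir * S_i + b0_ir + b1_ir * x + noise,

    with S_i the clean mixture spectrum, m ~ 1 + N(0, scatter_sd) a
    multiplicative scatter factor, b0/b1 ~ N(0, baseline_sd) an additive
    offset and tilt (x is the axis rescaled to [-1, 1]), and i.i.d.
    N(0, noise_sd) detector noise.
    """
    truth = getattr(chem, "truth", None)
    if truth is None:
        truth = chem.unit_means()[RESPONSES]
    names = [g.name for g in config.grids]
    if grid.name in names:
        stream = names.index(grid.name) + 1
    else:
        stream = len(names) + 1
    rng = np.random.default_rng([config.seed, stream])

    clean = clean_spectra(truth, grid, config)
    n, p = clean.shape
    axis = grid.axis()
    tilt = (axis - axis.mean()) / (0.5 * (axis[-1] - axis[0]))

    blocks, unit_ids, reps = [], [], []
    for rep in range(1, config.n_replicates_spectra + 1):
        m = 1.0 + config.scatter_sd * rng.standard_normal((n, 1))
        b0 = config.baseline_sd * rng.standard_normal((n, 1))
        b1 = config.baseline_sd * rng.standard_normal((n, 1))
        noise = config.noise_sd * rng.standard_normal((n, p))
        blocks.append(m * clean + b0 + b1 * tilt + noise)
        unit_ids.append(truth.index.to_numpy())
        reps.append(np.full(n, rep))

    order = np.lexsort(
        (np.concatenate(reps), np.concatenate(unit_ids))
    )  # group replicates per unit
    return SpectraBlock(
        instrument_name=grid.name,
        axis=axis,
        axis_unit=grid.axis_unit,
        unit_ids=np.concatenate(unit_ids)[order],
        replicates=np.concatenate(reps)[order],
        A=np.vstack(blocks)[order],
    )


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[ChemTable, dict[str, SpectraBlock]]:
    """Full campaign: chemistry plus one spectra block per configured grid."""
    chem = draw_chemistry(config)
    blocks = {g.name: render_spectra(chem, g, config) for g in config.grids}
    return chem, blocks
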