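"""Synthetic serum SERS spectra with known ground truth.

Reference component spectra are built as sums of pseudo-Voigt bands at
the positions reported for the serum SERS pattern: free uric acid
(prominent 638 cm^-1 band plus purine-ring bands at 867, 1002, 1055,
1125 and 1192 cm^-1), HSA-bound uric acid (same ring bands with an
additional intense C6=O stretching band at 1659 cm^-1) and hypoxanthine
(725 cm^-1).  Relative band amplitudes, widths (default FWHM 12 cm^-1)
and the Gaussian/Lorentzian mixing fraction (default eta = 0.7,
Lorentzian-dominant, typical of SERS bandwidths) are documented
generator parameters, not claims about the true compounds.

Donor cohorts are non-negative mixtures of the references with
per-donor concentration variability, a smooth polynomial background,
additive Gaussian noise and a global intensity scale factor:

    y_i = g_i * ( sum_k c_ik r_k comp_k(nu - s_k) + poly_i(nu) + eps_i )

Uric acid concentrations are drawn as one total (log-normal, median
280 uM, the average physiological value) split into free and HSA-bound
forms by a logit-normal bound fraction, reflecting albumin binding;
hypoxanthine is independent (log-normal, median 10 uM, geometric sd 2,
wide enough to span the 2.3-30 uM physiological range).  The generator
is a pure function of (config, seed).

Spiking scenarios return an (unspiked, spiked) pair sharing one noise
realization; isotopologue scenarios substitute band centers (e.g.
1659 -> 1653 cm^-1 for uric acid-2-13C,1,3,7-15N3) leaving everything
else unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import Spectrum, SpectrumSet, WavenumberAxis, default_axis
from .decompose import ComponentLibrary, shift_component

__all__ = [
    "Band",
    "BandTable",
    "CohortConfig",
    "DEFAULT_BAND_TABLES",
    "ISOTOPOLOGUE_SHIFTS",
    "build_reference",
    "default_library",
    "noise_sd_for_snr",
    "generate_cohort",
    "generate_ratio_cohort",
    "simulate_spike",
    "isotopologue_bands",
]


@dataclass(frozen=True)
class Band:
    """One pseudo-Voigt band: center/FWHM in cm^-1, unit-peak amplitude."""

    center: float
    fwhm: float = 12.0
    amplitude: float = 1.0
    eta: float = 0.7  # Lorentzian fraction

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"band at {self.center}: fwhm must be > 0")
        if self.amplitude <= 0:
            raise ValueError(f"band at {self.center}: amplitude must be > 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"band at {self.center}: eta must be in [0, 1]")


@dataclass(frozen=True)
class BandTable:
    """An ordered collection of bands defining one component spectrum."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))

    @classmethod
    def from_rows(cls, rows) -> "BandTable":
        """Build from (center[, fwhm[, amplitude[, eta]]]) rows."""
        return cls(tuple(Band(*row) for row in rows))

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def centers(self) -> np.ndarray:
        return np.asarray([b.center for b in self.bands])


# Relative amplitudes are generator plumbing set by eye to the relative
# band heights of serum-style SERS spectra (secondary uric-acid bands
# 30-60% of the 638 band); centers are the reported band positions.
DEFAULT_BAND_TABLES: dict[str, BandTable] = {
    "uric_acid_free": BandTable.from_rows(
        [(638, 12, 1.00), (867, 12, 0.40), (1002, 12, 0.35),
         (1055, 12, 0.30), (1125, 12, 0.50), (1192, 12, 0.40)]
    ),
    "uric_acid_bound": BandTable.from_rows(
        [(638, 12, 0.90), (867, 12, 0.36), (1002, 12, 0.33),
         (1055, 12, 0.34), (1125, 12, 0.62), (1192, 12, 0.50),
         (1659, 12, 0.85)]
    ),
    "hypoxanthine": BandTable.from_rows(
        [(725, 12, 1.00), (1090, 12, 0.18), (1580, 12, 0.22)]
    ),
}

# Measured downshift for the C6=O band is 6 cm^-1; the C-N stretching
# bands show larger downshifts (magnitudes here are plumbing defaults).
ISOTOPOLOGUE_SHIFTS: dict[float, float] = {
    1659: 1653, 867: 857, 1002: 992, 1055: 1045, 1125: 1114, 1192: 1181,
}


def _pseudo_voigt(x: np.ndarray, band: Band) -> np.ndarray:
    half = band.fwhm / 2.0
    d = x - band.center
    lorentz = half**2 / (d**2 + half**2)
    gauss = np.exp(-4.0 * math.log(2.0) * (d / band.fwhm) ** 2)
    return band.amplitude * (band.eta * lorentz + (1.0 - band.eta) * gauss)


def build_reference(
    bands: BandTable, axis: WavenumberAxis, normalize: bool = True
) -> Spectrum:
    """Sum of pseudo-Voigt profiles, vector-normalized by default.

    Isolated bands peak at the grid point nearest their table center.
    """
    if len(bands) == 0:
        raise ValueError("cannot build a reference from an empty band table")
    for b in bands.bands:
        if not axis.lo <= b.center <= axis.hi:
            raise ValueError(
                f"band center {b.center} outside axis [{axis.lo}, {axis.hi}]"
            )
    y = np.zeros(len(axis))
    for b in bands.bands:
        y += _pseudo_voigt(axis.values, b)
    if normalize:
        y = y / np.linalg.norm(y)
    return Spectrum(axis, y)


def default_library(axis: WavenumberAxis | None = None) -> ComponentLibrary:
    """The three-component serum library: free uric acid, HSA-bound uric
    acid, hypoxanthine -- unit-normalized on the given axis."""
    axis = default_axis() if axis is None else axis
    named = [
        (name, build_reference(table, axis))
        for name, table in DEFAULT_BAND_TABLES.items()
    ]
    return ComponentLibrary.from_spectra(named)


# -- cohort generation -------------------------------------------------------

#: median uM and geometric sd per component (uric acid forms are re-drawn
#: jointly from the total/bound-fraction law below when using generate_cohort
#: defaults via donors-style configs)
DEFAULT_CONCENTRATIONS: dict[str, tuple[float, float]] = {
    "uric_acid_free": (100.0, 1.3),
    "uric_acid_bound": (180.0, 1.3),
    "hypoxanthine": (10.0, 2.0),
}

#: intensity units per uM; hypoxanthine's larger coefficient (it adsorbs
#: efficiently on Ag) makes the median serum-like 725:638 height ratio
#: ~0.5, within the range shown by serum SERS spectra
DEFAULT_RESPONSES: dict[str, float] = {
    "uric_acid_free": 1.0,
    "uric_acid_bound": 1.0,
    "hypoxanthine": 9.0,
}

#: uniform ranges for the polynomial background coefficients c0..c4,
#: evaluated on the axis rescaled to [0, 1]
DEFAULT_BASELINE_RANGES: tuple[tuple[float, float], ...] = (
    (20.0, 60.0), (-20.0, 20.0), (-10.0, 10.0), (-5.0, 5.0), (-5.0, 5.0),
)

UA_TOTAL_MEDIAN_UM = 280.0  # average physiological uric acid
UA_TOTAL_GSD = 1.3
UA_BOUND_FRACTION_MEAN = 0.64
UA_BOUND_FRACTION_LOGIT_SD = 0.10  # albumin binding keeps the split tight


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic donor cohort."""

    n_donors: int = 81
    concentrations: dict = field(default_factory=lambda: dict(DEFAULT_CONCENTRATIONS))
    responses: dict = field(default_factory=lambda: dict(DEFAULT_RESPONSES))
    baseline_ranges: tuple = DEFAULT_BASELINE_RANGES
    noise_sd: float = 1.16  # ~SNR 50 on the 638 band at median concentrations
    scale: tuple[float, float] = (1.0, 1.5)  # lognormal median, geometric sd
    component_shifts: dict = field(default_factory=dict)  # cm^-1 per component
    couple_uric_forms: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, (_, gsd) in self.concentrations.items():
            if gsd < 1.0:
                raise ValueError(f"{name}: geometric sd must be >= 1")


def noise_sd_for_snr(
    snr: float,
    library: ComponentLibrary,
    concentrations: dict | None = None,
    responses: dict | None = None,
    band: float = 638.0,
) -> float:
    """Noise sd realizing a given SNR on a band at median concentrations.

    SNR is defined on the dominant serum band (638 cm^-1 by default):
    the median-mixture signal height there divided by the noise sd.
    """
    concentrations = DEFAULT_CONCENTRATIONS if concentrations is None else concentrations
    responses = DEFAULT_RESPONSES if responses is None else responses
    signal = np.zeros(len(library.axis))
    for name, (median, _) in concentrations.items():
        signal += median * responses.get(name, 1.0) * library.component(name)
    return float(signal[library.axis.nearest_index(band)] / snr)


def _draw_concentrations(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-donor concentration table (uM)."""
    n = config.n_donors
    cols: dict[str, np.ndarray] = {}
    names = list(config.concentrations)
    coupled = (
        config.couple_uric_forms
        and "uric_acid_free" in names
        and "uric_acid_bound" in names
    )
    if coupled:
        total = rng.lognormal(math.log(UA_TOTAL_MEDIAN_UM), math.log(UA_TOTAL_GSD), n)
        logit = rng.normal(
            math.log(UA_BOUND_FRACTION_MEAN / (1 - UA_BOUND_FRACTION_MEAN)),
            UA_BOUND_FRACTION_LOGIT_SD,
            n,
        )
        frac = 1.0 / (1.0 + np.exp(-logit))
        cols["uric_acid_free"] = total * (1.0 - frac)
        cols["uric_acid_bound"] = total * frac
    for name in names:
        if name in cols:
            continue
        median, gsd = config.concentrations[name]
        cols[name] = rng.lognormal(math.log(median), math.log(gsd), n)
    return pd.DataFrame({name: cols[name] for name in names})


def _baseline(config: CohortConfig, axis: WavenumberAxis, rng: np.random.Generator) -> np.ndarray:
    t = (axis.values - axis.lo) / (axis.hi - axis.lo)
    y = np.zeros(len(axis))
    for power, (lo, hi) in enumerate(config.baseline_ranges):
        y += rng.uniform(lo, hi) * t**power
    return y


def _mixture(
    concentrations: dict[str, float],
    config: CohortConfig,
    library: ComponentLibrary,
) -> np.ndarray:
    y = np.zeros(len(library.axis))
    for name, conc in concentrations.items():
        comp = library.component(name)
        s = config.component_shifts.get(name, 0.0)
        if s != 0.0:
            comp = shift_component(comp, library.axis, s, bound=None)
        y += conc * config.responses.get(name, 1.0) * comp
    return y


def generate_cohort(
    config: CohortConfig,
    library: ComponentLibrary,
    concentrations: pd.DataFrame | None = None,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Generate a donor cohort and its ground-truth table.

    Returns ``(spectra, truth)`` where ``truth`` holds the per-donor
    concentrations (uM), the global scale factor and the seed.  The
    same config (and seed) always reproduces the same output bitwise.
    """
    rng = np.random.default_rng(config.seed)
    conc = _draw_concentrations(config, rng) if concentrations is None else concentrations.copy()
    if len(conc) != config.n_donors:
        raise ValueError("concentration table length must equal n_donors")
    scale = rng.lognormal(math.log(config.scale[0]), math.log(config.scale[1]), config.n_donors) \
        if config.scale[1] > 1.0 else np.full(config.n_donors, config.scale[0])

    spectra: list[Spectrum] = []
    for i in range(config.n_donors):
        signal = _mixture({n: conc[n].iloc[i] for n in conc.columns}, config, library)
        base = _baseline(config, library.axis, rng)
        noise = rng.normal(0.0, config.noise_sd, len(library.axis)) if config.noise_sd > 0 else 0.0
        y = scale[i] * (signal + base + noise)
        spectra.append(
            Spectrum(library.axis, y, {"sample": f"donor{i:03d}", "seed": config.seed})
        )
    truth = conc.copy()
    truth.insert(0, "id", [s.meta["sample"] for s in spectra])
    truth["scale"] = scale
    truth["seed"] = config.seed
    return SpectrumSet(spectra, library.axis), truth


def generate_ratio_cohort(
    n_donors: int,
    library: ComponentLibrary,
    f_range: tuple[float, float] = (0.2, 0.8),
    total_amplitude: float = 280.0,
    bound_fraction: float = UA_BOUND_FRACTION_MEAN,
    noise_sd: float = 1.16,
    seed: int = 0,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Cohort in which the uric-acid : hypoxanthine signal ratio varies.

    Each donor's signal is ``A * (f * uric + (1-f) * hypoxanthine)``
    with the uric part split between free and bound forms at a fixed
    fraction and ``f`` drawn uniformly from ``f_range``.  Designed for
    studying how a varying metabolite ratio shows up in PCA loadings.
    """
    rng = np.random.default_rng(seed)
    f = rng.uniform(*f_range, n_donors)
    conc = pd.DataFrame(
        {
            "uric_acid_free": total_amplitude * f * (1 - bound_fraction),
            "uric_acid_bound": total_amplitude * f * bound_fraction,
            "hypoxanthine": total_amplitude * (1 - f) / DEFAULT_RESPONSES["hypoxanthine"],
        }
    )
    config = CohortConfig(
        n_donors=n_donors,
        noise_sd=noise_sd,
        scale=(1.0, 1.0),
        seed=seed,
    )
    sset, truth = generate_cohort(config, library, concentrations=conc)
    truth["f_uric"] = f
    return sset, truth


def simulate_spike(
    base_concentrations: dict[str, float],
    analyte: str,
    added: float,
    config: CohortConfig,
    library: ComponentLibrary,
) -> tuple[Spectrum, Spectrum]:
    """Simulate a spiking experiment: (unspiked, spiked) spectrum pair.

    Both spectra share the same baseline, noise realization and scale
    factor and differ only in the analyte concentration.  ``analyte``
    is a component name, or ``"uric_acid"`` to distribute the added
    concentration over the free and HSA-bound forms proportionally to
    their base concentrations (binding partitioning).
    """
    if added < 0:
        raise ValueError("added concentration must be >= 0")
    if analyte in library.names:
        additions = {analyte: added}
    elif analyte == "uric_acid":
        forms = [n for n in library.names if n.startswith("uric_acid")]
        if not forms:
            raise KeyError(f"no uric acid components in library {library.names}")
        base_total = sum(base_concentrations.get(n, 0.0) for n in forms)
        if base_total == 0:
            additions = {n: added / len(forms) for n in forms}
        else:
            additions = {
                n: added * base_concentrations.get(n, 0.0) / base_total for n in forms
            }
    else:
        raise KeyError(f"unknown analyte {analyte!r}; library has {library.names}")

    rng = np.random.default_rng(config.seed)
    base = _baseline(config, library.axis, rng)
    noise = rng.normal(0.0, config.noise_sd, len(library.axis)) if config.noise_sd > 0 else 0.0
    scale = (
        rng.lognormal(math.log(config.scale[0]), math.log(config.scale[1]))
        if config.scale[1] > 1.0
        else config.scale[0]
    )
    names = list(base_concentrations) + [
        n for n in additions if n not in base_concentrations
    ]
    spiked_conc = {
        n: base_concentrations.get(n, 0.0) + additions.get(n, 0.0) for n in names
    }
    out = []
    for label, conc in (("unspiked", base_concentrations), ("spiked", spiked_conc)):
        y = scale * (_mixture(conc, config, library) + base + noise)
        out.append(
            Spectrum(library.axis, y, {"sample": label, "analyte": analyte, "added": added})
        )
    return out[0], out[1]


def isotopologue_bands(
    bands: BandTable, shift_map: dict[float, float]
) -> BandTable:
    """Substitute band centers per an isotopologue shift map.

    Every key must match an existing center exactly; widths, amplitudes
    and mixing fractions are preserved.
    """
    centers = set(bands.centers.tolist())
    for old in shift_map:
        if old not in centers:
            raise KeyError(f"no band at {old} cm^-1 in table (centers: {sorted(centers)})")
    new = tuple(
        replace(b, center=shift_map.get(b.center, b.center)) for b in bands.bands
    )
    return BandTable(new)
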