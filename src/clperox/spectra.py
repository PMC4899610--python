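"""UV absorbance time series and their conversion to concentration traces.

The instrument model is a double-beam UV spectrophotometer recording
spectra of a liposome suspension over 210-300 nm every few minutes
against a reference cuvette.  Two quantities are extracted:

* conjugated dienes, the primary peroxidation product, from the 234-nm
  band via Beer-Lambert with eps = 27400 M^-1 cm^-1;
* antioxidant expenditure, from the oxidized-minus-reduced difference
  band of the quinone headgroup (281 nm for ubiquinone).

Supported file layouts (comma-separated, explicit headers):

* wide  -- ``time_min,<lambda1>,<lambda2>,...`` one column per wavelength;
* long  -- ``time_min,wavelength_nm,absorbance`` one row per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .antioxidants import AntioxidantSpec
from .errors import (
    ConfigurationError,
    DomainError,
    SpectralFormatError,
    ValidationError,
    WavelengthLookupError,
)

#: Molar absorptivity of conjugated dienes at 234 nm, M^-1 cm^-1.
EPSILON_DIENE_234 = 27400.0

#: Wavelength at which conjugated dienes are monitored, nm.
DIENE_WAVELENGTH = 234.0

#: Typical instrument noise of the setup, absorbance units (1 sigma).
DEFAULT_NOISE_SD = 0.002

#: Default cuvette path length, cm (standard 1-cm quartz cuvette).
DEFAULT_PATH_CM = 1.0

_WAVELENGTH_TOL_NM = 1.0


@dataclass
class SpectralTimeSeries:
    """Absorbance as a function of time and wavelength.

    Attributes
    ----------
    times : ndarray, minutes, strictly increasing, >= 0
    wavelengths : ndarray, nm, strictly increasing
    absorbance : ndarray, shape (n_times, n_wavelengths), absorbance units
    meta : dict
        Free-form acquisition metadata.  Recognised keys:
        ``temperature_C``, ``path_cm`` (> 0), ``reference_subtracted``.
    """

    times: np.ndarray
    wavelengths: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.ndim != 1 or self.wavelengths.ndim != 1:
            raise ValidationError("times and wavelengths must be 1-D")
        if self.absorbance.shape != (self.times.size, self.wavelengths.size):
            raise ValidationError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"(n_times={self.times.size}, n_wavelengths={self.wavelengths.size})"
            )
        if self.times.size and self.times[0] < 0:
            raise ValidationError("times must be >= 0")
        bad = np.flatnonzero(np.diff(self.times) <= 0)
        if bad.size:
            raise ValidationError(
                f"times must be strictly increasing; violation at index {bad[0] + 1}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if self.path_cm <= 0:
            raise ValidationError("path length must be > 0")

    @property
    def path_cm(self) -> float:
        return float(self.meta.get("path_cm", DEFAULT_PATH_CM))

    def wavelength_index(self, wavelength: float, tol: float = _WAVELENGTH_TOL_NM) -> int:
        """Index of the nearest recorded wavelength column within ``tol`` nm."""
        if self.wavelengths.size == 0:
            raise WavelengthLookupError("series has no wavelength columns")
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[i] - wavelength) > tol:
            raise WavelengthLookupError(
                f"no recorded wavelength within {tol} nm of {wavelength} nm "
                f"(range {self.wavelengths[0]}-{self.wavelengths[-1]} nm)"
            )
        return i

    def at_wavelength(self, wavelength: float) -> np.ndarray:
        """Absorbance-vs-time column at the nearest recorded wavelength."""
        return self.absorbance[:, self.wavelength_index(wavelength)]


@dataclass
class KineticTrace:
    """A single-species concentration-vs-time series in molar units."""

    times: np.ndarray
    values: np.ndarray
    species: str = ""
    uncertainty: np.ndarray | None = None
    #: 1-sigma concentration equivalent of instrument noise, M (0 = unknown)
    noise_equivalent: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValidationError("times and values must have matching shapes")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("trace values must be finite")
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)
            if self.uncertainty.shape != self.values.shape:
                raise ValidationError("uncertainty must match values in shape")
        # Small negatives from noise are retained so rate fits stay unbiased,
        # but excursions beyond -3 sigma suggest a baseline problem.
        if self.noise_equivalent > 0 and self.values.size:
            floor = -3.0 * self.noise_equivalent
            if self.values.min() < floor:
                warnings.warn(
                    f"trace {self.species!r} dips below -3 sigma noise "
                    f"equivalent ({self.values.min():.3g} M < {floor:.3g} M); "
                    "check the baseline",
                    stacklevel=2,
                )

    def window(self, t_start: float, t_end: float) -> "KineticTrace":
        """Sub-trace with t_start <= t <= t_end (inclusive)."""
        m = (self.times >= t_start) & (self.times <= t_end)
        return KineticTrace(
            self.times[m],
            self.values[m],
            self.species,
            None if self.uncertainty is None else self.uncertainty[m],
            self.noise_equivalent,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "concentration_M": self.values,
                "species": self.species,
            }
        )


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def _read_csv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SpectralFormatError(f"{path}: file is empty") from None
    except (pd.errors.ParserError, OSError) as exc:
        raise SpectralFormatError(f"{path}: {exc}") from exc
    if df.empty:
        raise SpectralFormatError(f"{path}: no data rows")
    return df


def _sniff_dialect(df: pd.DataFrame) -> str:
    cols = [c.strip().lower() for c in df.columns]
    if cols[:3] == ["time_min", "wavelength_nm", "absorbance"]:
        return "long"
    if cols and cols[0] == "time_min":
        return "wide"
    raise SpectralFormatError(
        "unrecognised header: expected 'time_min,wavelength_nm,absorbance' "
        "(long) or 'time_min,<wavelengths...>' (wide)"
    )


def load_spectral_series(path, dialect: str = "auto", meta: dict | None = None) -> SpectralTimeSeries:
    """Read a spectral CSV into a validated :class:`SpectralTimeSeries`.

    Parameters
    ----------
    path : str or Path
        CSV file in wide or long layout (see module docstring).
    dialect : {"auto", "wide", "long"}
        Layout; ``"auto"`` sniffs the header.
    meta : dict, optional
        Extra metadata merged into the series (e.g. ``path_cm``).

    Raises
    ------
    SpectralFormatError
        Missing file content, unknown header, duplicated time points.
    ValidationError
        Non-monotone times (message carries the offending index).
    """
    path = Path(path)
    if not path.exists():
        raise SpectralFormatError(f"{path}: file does not exist")
    df = _read_csv(path)
    if dialect == "auto":
        dialect = _sniff_dialect(df)

    if dialect == "long":
        df.columns = [c.strip().lower() for c in df.columns]
        required = {"time_min", "wavelength_nm", "absorbance"}
        if not required.issubset(df.columns):
            raise SpectralFormatError(f"{path}: long layout requires columns {sorted(required)}")
        dup = df.duplicated(subset=["time_min", "wavelength_nm"])
        if dup.any():
            raise SpectralFormatError(
                f"{path}: duplicated (time, wavelength) sample at row {int(np.flatnonzero(dup)[0])}"
            )
        wide = df.pivot(index="time_min", columns="wavelength_nm", values="absorbance")
        if wide.isna().any().any():
            raise SpectralFormatError(f"{path}: long layout is not a complete time x wavelength grid")
        times = wide.index.to_numpy(dtype=float)
        wavelengths = wide.columns.to_numpy(dtype=float)
        matrix = wide.to_numpy(dtype=float)
    elif dialect == "wide":
        tcol = df.columns[0]
        try:
            wavelengths = np.array([float(c) for c in df.columns[1:]])
        except ValueError:
            raise SpectralFormatError(
                f"{path}: wide layout requires numeric wavelength column headers"
            ) from None
        if wavelengths.size == 0:
            raise SpectralFormatError(f"{path}: wide layout has no wavelength columns")
        times = df[tcol].to_numpy(dtype=float)
        if pd.Series(times).duplicated().any():
            raise SpectralFormatError(f"{path}: duplicated time points")
        order = np.argsort(wavelengths)
        wavelengths = wavelengths[order]
        matrix = df.iloc[:, 1:].to_numpy(dtype=float)[:, order]
    else:
        raise SpectralFormatError(f"unknown dialect {dialect!r}")

    full_meta = {"source": str(path), "time_unit": "min", "wavelength_unit": "nm"}
    if meta:
        full_meta.update(meta)
    return SpectralTimeSeries(times, wavelengths, matrix, full_meta)


def write_spectral_series(series: SpectralTimeSeries, path, dialect: str = "wide") -> Path:
    """Write a series to CSV in the requested layout; returns the path."""
    path = Path(path)
    if dialect == "wide":
        df = pd.DataFrame(series.absorbance, columns=[f"{w:g}" for w in series.wavelengths])
        df.insert(0, "time_min", series.times)
        df.to_csv(path, index=False, float_format="%.17g")
    elif dialect == "long":
        tt, ww = np.meshgrid(series.times, series.wavelengths, indexing="ij")
        pd.DataFrame(
            {
                "time_min": tt.ravel(),
                "wavelength_nm": ww.ravel(),
                "absorbance": series.absorbance.ravel(),
            }
        ).to_csv(path, index=False, float_format="%.17g")
    else:
        raise SpectralFormatError(f"unknown dialect {dialect!r}")
    return path


def write_trace(trace: KineticTrace, path) -> Path:
    """Write a kinetic trace as ``time_min,concentration_M,species`` CSV."""
    path = Path(path)
    trace.to_frame().to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Beer-Lambert conversions
# ---------------------------------------------------------------------------

def absorbance_to_concentration(a, epsilon: float, path_length: float = DEFAULT_PATH_CM):
    """Beer-Lambert inversion: concentration = A / (epsilon * l).

    Works elementwise on arrays.  ``epsilon`` in M^-1 cm^-1 and
    ``path_length`` in cm must both be positive.
    """
    if not epsilon > 0:
        raise DomainError(f"extinction coefficient must be > 0, got {epsilon}")
    if not path_length > 0:
        raise DomainError(f"path length must be > 0, got {path_length}")
    return np.asarray(a, dtype=float) / (epsilon * path_length)


def diene_trace(
    series: SpectralTimeSeries,
    wavelength: float = DIENE_WAVELENGTH,
    baseline="first",
    epsilon: float = EPSILON_DIENE_234,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> KineticTrace:
    """Conjugated-diene concentration trace from the 234-nm absorbance.

    ``baseline`` is either ``"first"`` (subtract the absorbance at the first
    recorded time point; the reference cuvette removes static components but
    not the t=0 offset) or an explicit absorbance value.
    """
    a = series.at_wavelength(wavelength).astype(float)
    if isinstance(baseline, str):
        if baseline != "first":
            raise ConfigurationError(f"unknown baseline policy {baseline!r}")
        a0 = a[0] if a.size else 0.0
    else:
        a0 = float(baseline)
    conc = absorbance_to_concentration(a - a0, epsilon, series.path_cm)
    return KineticTrace(
        series.times,
        conc,
        species="conjugated dienes",
        noise_equivalent=noise_sd / (epsilon * series.path_cm),
    )


@dataclass
class OxidizedTrace:
    """Quinone (oxidized antioxidant) trace plus its saturation time."""

    trace: KineticTrace
    #: first time (min) from which the trace stays within noise of its final value
    plateau_min: float


def antioxidant_trace(
    series: SpectralTimeSeries,
    spec: AntioxidantSpec,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> OxidizedTrace:
    """Oxidized-antioxidant concentration from the difference band.

    The difference absorbance at ``spec.monitor_wavelength`` divided by the
    oxidized-minus-reduced coefficient gives [Q](t); the saturation
    (plateau) time marks antioxidant exhaustion.
    """
    if spec.epsilon_diff_monitor is None:
        raise ConfigurationError(
            f"{spec.name}: no difference extinction coefficient configured "
            "for the monitor wavelength"
        )
    a = series.at_wavelength(spec.monitor_wavelength)
    conc = absorbance_to_concentration(a, spec.epsilon_diff_monitor, series.path_cm)
    noise_eq = noise_sd / (spec.epsilon_diff_monitor * series.path_cm)
    trace = KineticTrace(
        series.times, conc, species=f"{spec.name} (oxidized)", noise_equivalent=noise_eq
    )
    span = float(conc.max() - conc.min()) if conc.size else 0.0
    tol = max(3.0 * noise_eq, 0.01 * span)
    final = conc[-1]
    stable = np.abs(conc - final) <= tol
    # first index from which every later point is stable
    idx = len(conc)
    for i in range(len(conc) - 1, -1, -1):
        if stable[i]:
            idx = i
        else:
            break
    plateau = float(series.times[idx]) if idx < len(conc) else float(series.times[-1])
    return OxidizedTrace(trace, plateau)


# ---------------------------------------------------------------------------
# Isosbestic points
# ---------------------------------------------------------------------------

@dataclass
class IsosbesticResult:
    """Wavelengths where oxidized and reduced spectra cross."""

    wavelengths_nm: list
    degenerate: bool = False

    def __iter__(self):
        return iter(self.wavelengths_nm)

    def __len__(self):
        return len(self.wavelengths_nm)


def _as_spectrum(spec) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(spec, pd.Series):
        return spec.index.to_numpy(dtype=float), spec.to_numpy(dtype=float)
    if isinstance(spec, dict):
        wl = np.array(sorted(spec), dtype=float)
        return wl, np.array([spec[w] for w in wl], dtype=float)
    wl, eps = spec
    return np.asarray(wl, dtype=float), np.asarray(eps, dtype=float)


def find_isosbestic(ox_spectrum, red_spectrum, window: tuple[float, float] = (230.0, 240.0)) -> IsosbesticResult:
    """Locate isosbestic points of an oxidized/reduced spectral pair.

    Both spectra must be sampled on a common wavelength grid.  Crossings of
    ``eps_ox - eps_red`` inside ``window`` are located by linear
    interpolation.  If the difference vanishes everywhere in the window the
    result is flagged degenerate and carries the window endpoints.
    """
    wl_ox, eps_ox = _as_spectrum(ox_spectrum)
    wl_red, eps_red = _as_spectrum(red_spectrum)
    if wl_ox.shape != wl_red.shape or not np.allclose(wl_ox, wl_red):
        raise ValidationError("oxidized and reduced spectra are on mismatched grids")
    lo, hi = window
    m = (wl_ox >= lo) & (wl_ox <= hi)
    wl, diff = wl_ox[m], (eps_ox - eps_red)[m]
    if wl.size < 2:
        return IsosbesticResult([])
    scale = max(np.abs(eps_ox[m]).max(), np.abs(eps_red[m]).max(), 1.0)
    if np.all(np.abs(diff) <= 1e-12 * scale):
        return IsosbesticResult([float(wl[0]), float(wl[-1])], degenerate=True)
    points = []
    for i in range(wl.size - 1):
        a, b = diff[i], diff[i + 1]
        if a == 0.0:
            points.append(float(wl[i]))
        elif a * b < 0:
            points.append(float(wl[i] - a * (wl[i + 1] - wl[i]) / (b - a)))
    if diff[-1] == 0.0:
        points.append(float(wl[-1]))
    return IsosbesticResult(points)
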