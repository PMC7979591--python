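"""Physics of the multi-echo chemical-shift-encoded magnitude signal.

The forward model for a voxel containing water and fat with a common
effective transverse relaxation rate is

    nu(t) = |w + c(t) * f| * exp(-r2star * t)

where ``c(t)`` is the complex fat dephasing factor obtained by summing the
fat spectral peaks, and what a magnitude image actually shows is the mean
of a Rice distribution with location ``nu`` and scale ``sigma``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.special import ive

__all__ = [
    "GAMMA_BAR_HZ_PER_T",
    "Protocol",
    "FatSpectrum",
    "TissueState",
    "NoiseModel",
    "EchoSeries",
    "fat_dephasing",
    "noiseless_magnitude",
    "rician_expectation",
    "expected_signal",
    "load_protocol",
    "load_protocols",
]

#: Proton gyromagnetic ratio over 2*pi, in Hz per tesla.
GAMMA_BAR_HZ_PER_T = 42.577e6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Protocol:
    """An echo-train specification for one multi-echo gradient-echo sequence.

    Times are stored in seconds.  ``extras`` holds acquisition metadata
    (TR, flip angle, bandwidth, ...) that the signal model deliberately
    ignores: the model has no longitudinal-relaxation term.
    """

    name: str
    initial_te: float
    delta_te: float
    n_echoes: int
    field_strength: float = 1.5
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.initial_te > 0:
            raise ValueError("initial_te must be > 0")
        if not self.delta_te > 0:
            raise ValueError("delta_te must be > 0")
        if self.n_echoes < 3:
            raise ValueError("n_echoes must be >= 3")
        if not self.field_strength > 0:
            raise ValueError("field_strength must be > 0")

    @classmethod
    def from_ms(cls, name: str, initial_te_ms: float, delta_te_ms: float,
                n_echoes: int, field_strength: float = 1.5,
                extras: dict | None = None) -> "Protocol":
        """Build a protocol from echo times given in milliseconds."""
        return cls(name, initial_te_ms * 1e-3, delta_te_ms * 1e-3,
                   n_echoes, field_strength, extras or {})

    @property
    def echo_times(self) -> np.ndarray:
        """Echo times in seconds, strictly increasing, length ``n_echoes``."""
        return self.initial_te + self.delta_te * np.arange(self.n_echoes)


@dataclass(frozen=True)
class FatSpectrum:
    """Multi-peak fat spectrum: (chemical shift in ppm vs water, amplitude).

    Amplitudes are unitless fractions summing to one.
    """

    peaks: tuple[tuple[float, float], ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.peaks) == 0:
            raise ValueError("spectrum must have at least one peak")
        shifts = np.array([p[0] for p in self.peaks], dtype=float)
        amps = np.array([p[1] for p in self.peaks], dtype=float)
        if not np.all(np.isfinite(shifts)):
            raise ValueError("peak shifts must be finite")
        if abs(amps.sum() - 1.0) > 1e-9:
            raise ValueError("peak amplitudes must sum to 1 (within 1e-9)")

    @property
    def shifts_ppm(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks], dtype=float)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks], dtype=float)

    @classmethod
    def default(cls) -> "FatSpectrum":
        """The packaged six-peak liver fat spectrum."""
        ref = resources.files("liveriron.data").joinpath("fat_spectrum.json")
        doc = json.loads(ref.read_text())
        peaks = tuple((float(p["shift_ppm"]), float(p["amplitude"]))
                      for p in doc["peaks"])
        return cls(peaks=peaks, name=doc.get("name", "default"))

    @classmethod
    def single_peak(cls, shift_ppm: float = -3.4) -> "FatSpectrum":
        return cls(peaks=((float(shift_ppm), 1.0),), name="single-peak")

    def to_json(self) -> str:
        return json.dumps({"name": self.name,
                           "peaks": [{"shift_ppm": s, "amplitude": a}
                                     for s, a in self.peaks]}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FatSpectrum":
        doc = json.loads(text)
        return cls(peaks=tuple((float(p["shift_ppm"]), float(p["amplitude"]))
                               for p in doc["peaks"]),
                   name=doc.get("name", "custom"))


@dataclass(frozen=True)
class TissueState:
    """Per-voxel (or per-ROI) ground truth: water, fat, relaxation rate."""

    w: float
    f: float
    r2star: float

    def __post_init__(self) -> None:
        for v, label in ((self.w, "w"), (self.f, "f"), (self.r2star, "r2star")):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{label} must be finite and >= 0")

    @property
    def pdff(self) -> float:
        total = self.w + self.f
        if total <= 0:
            return float("nan")
        return self.f / total


@dataclass(frozen=True)
class NoiseModel:
    """Known magnitude-noise level (scalar standard deviation)."""

    sigma: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError("sigma must be finite and >= 0")


@dataclass(frozen=True)
class EchoSeries:
    """Magnitude samples at the protocol's echo times, for one voxel/ROI."""

    te: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self) -> None:
        te = np.asarray(self.te, dtype=float)
        mag = np.asarray(self.magnitude, dtype=float)
        if te.ndim != 1 or mag.ndim != 1 or te.shape != mag.shape:
            raise ValueError("te and magnitude must be 1-D and equal length")
        if np.any(np.diff(te) <= 0):
            raise ValueError("te must be strictly increasing")
        if np.any(mag < 0):
            raise ValueError("magnitude must be nonnegative")
        object.__setattr__(self, "te", te)
        object.__setattr__(self, "magnitude", mag)

    def __len__(self) -> int:
        return self.te.size


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def fat_dephasing(spectrum: FatSpectrum, te, field_strength: float = 1.5):
    """Complex fat dephasing factor at echo time(s) ``te`` (seconds).

    c(te) = sum_p a_p * exp(i * 2*pi * df_p * te), with the peak frequency
    offset df_p = shift_ppm * 1e-6 * gamma_bar * B0.  |c| <= 1 because the
    amplitudes sum to one.
    """
    te = np.asarray(te, dtype=float)
    if np.any(te < 0):
        raise ValueError("te must be >= 0")
    if not field_strength > 0:
        raise ValueError("field_strength must be > 0")
    df = spectrum.shifts_ppm * 1e-6 * GAMMA_BAR_HZ_PER_T * field_strength
    phase = 2.0 * np.pi * np.multiply.outer(te, df)
    c = (spectrum.amplitudes * np.exp(1j * phase)).sum(axis=-1)
    return c if c.ndim else complex(c)


def noiseless_magnitude(state: TissueState, c, te):
    """|w + c*f| * exp(-r2star * te): the noise-free magnitude signal."""
    te = np.asarray(te, dtype=float)
    if np.any(te < 0):
        raise ValueError("te must be >= 0")
    amp = np.abs(state.w + np.asarray(c) * state.f)
    out = amp * np.exp(-state.r2star * te)
    return out if out.ndim else float(out)


def rician_expectation(nu, sigma):
    """Mean of a Rice(nu, sigma) magnitude.

    Uses the closed form sigma*sqrt(pi/2)*L_{1/2}(-nu^2/(2 sigma^2))
    evaluated through exponentially scaled Bessel functions, which is
    stable for arbitrarily large nu/sigma:

        E = sigma*sqrt(pi/2) * [(1+t)*I0e(t/2) + t*I1e(t/2)],  t = nu^2/(2 sigma^2)

    where ``Ine`` are scaled modified Bessel functions.  ``sigma = 0``
    returns ``nu`` exactly.
    """
    nu = np.asarray(nu, dtype=float)
    scalar = nu.ndim == 0 and np.ndim(sigma) == 0
    sigma = np.asarray(sigma, dtype=float)
    if np.any(nu < 0) or np.any(sigma < 0):
        raise ValueError("nu and sigma must be >= 0")
    nu, sigma = np.broadcast_arrays(nu, sigma)
    out = np.array(nu, dtype=float, copy=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sigma > 0, nu ** 2 / (2.0 * sigma ** 2), np.inf)
    # scipy's scaled Bessel functions lose accuracy / return NaN for very
    # large arguments; switch to the asymptotic expansion there, where the
    # truncation error is far below 1e-12 relative.
    closed = (sigma > 0) & (t < 1e8)
    if np.any(closed):
        tc = t[closed]
        half = 0.5 * tc
        out[closed] = sigma[closed] * np.sqrt(np.pi / 2.0) * (
            (1.0 + tc) * ive(0, half) + tc * ive(1, half))
    asym = (sigma > 0) & (t >= 1e8)
    if np.any(asym):
        nua = nu[asym]
        s2 = sigma[asym] ** 2
        out[asym] = nua + s2 / (2.0 * nua) - s2 ** 2 / (8.0 * nua ** 3)
    return float(out) if scalar else out


def expected_signal(state: TissueState, spectrum: FatSpectrum,
                    protocol: Protocol, noise: NoiseModel) -> EchoSeries:
    """Expected magnitude series over the protocol's full echo train."""
    te = protocol.echo_times
    c = fat_dephasing(spectrum, te, protocol.field_strength)
    nu = noiseless_magnitude(state, c, te)
    return EchoSeries(te=te, magnitude=rician_expectation(nu, noise.sigma))


# ---------------------------------------------------------------------------
# protocol presets
# ---------------------------------------------------------------------------

def load_protocols() -> dict[str, Protocol]:
    """All packaged protocol presets, keyed by name."""
    ref = resources.files("liveriron.data").joinpath("protocols.json")
    doc = json.loads(ref.read_text())
    out = {}
    for name, entry in doc.items():
        out[name] = Protocol.from_ms(
            name=entry["name"],
            initial_te_ms=entry["initial_te_ms"],
            delta_te_ms=entry["delta_te_ms"],
            n_echoes=entry["n_echoes"],
            field_strength=entry.get("field_strength", 1.5),
            extras=entry.get("extras", {}),
        )
    return out


def load_protocol(name: str) -> Protocol:
    """One packaged protocol preset by name (``me-gre``, ``qdixon``, ``qdixon-wip``)."""
    protocols = load_protocols()
    try:
        return protocols[name]
    except KeyError:
        raise KeyError(f"unknown protocol {name!r}; "
                       f"available: {sorted(protocols)}") from None
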