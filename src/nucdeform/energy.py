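"""Bending and shearing deformation energies of DNA under superhelix constraints.

Nucleosomal DNA is modelled as a shearable elastic rod forced onto the ideal
superhelical path (radius 41.9 A, pitch 25.9 A).  Two global constraints drive
the deformation of a candidate window of odd length ``L`` centred on the
putative dyad:

* the total bend ``alpha`` (579 deg over the central 129 bp; 600 deg over the
  full 147 bp), realised by roll and tilt;
* the displacement ``S = 41.96 A`` along the superhelix screw axis, realised
  by slide and shift.

Each step responds harmonically and independently: under a uniform bending
torque ``F_b`` the roll of step *i* moves by ``F_b cos(Omega_i) / k_roll`` and
its tilt by ``F_b sin(Omega_i) / k_tilt``, where ``Omega_i`` is the cumulative
helical twist at the centre of step *i* counted from the dyad.  The torque is
fixed by requiring the phase-projected sum of realised roll/tilt over the
window to equal ``alpha``, giving the closed form

    F_b = (alpha - A0) / C,     E_bend = (alpha - A0)^2 / (2 C),

with ``A0 = sum(roll0 cos Omega + tilt0 sin Omega)`` the intrinsic projected
bend of the sequence and ``C = sum(cos^2 Omega / k_roll + sin^2 Omega /
k_tilt)`` its compliance.  Shearing is exactly analogous with slide ~ cos,
shift ~ sin, constraint ``S`` and constants k_slide/k_shift.  This is the
minimiser of the harmonic step energies subject to the linear constraint, so a
constrained quadratic programme provides an independent check.

Sequence dependence enters a third way through the twist: the equilibrium step
twists of the window are rescaled by a common factor so that they sum to
``(L-1) * omega_bar``, the total twist of nucleosome-bound DNA (omega_bar =
mean step twist of the 1kx5 crystal structure); the rescaled twists generate
the phases ``Omega_i``.

Deviations of roll with high positive equilibrium value placed where
``cos Omega_i`` is large reduce the required torque and hence the energy --
the physical content of 10-bp rotational positioning signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .params import ParamTable

#: Printed total-bend constraints (degrees) for the two published windows.
DEFAULT_ALPHA = {129: 579.0, 147: 600.0}

#: Pitch displacement of the ideal superhelix along its screw axis (Angstrom).
DEFAULT_S = 41.96

#: Mean base-pair-step twist of nucleosome-bound DNA in the 1kx5 crystal
#: structure (degrees); sets the reference total twist (L-1)*omega_bar.
OMEGA_BAR_1KX5 = 34.52

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a DNA string to base codes A,C,G,T -> 0..3; anything else -> -1."""
    return _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class EnergyModelConfig:
    """Window geometry and superhelix constraints.

    ``alpha`` defaults to the published value for L in {129, 147} and must be
    given explicitly for any other window length (the printed pair is not
    linear in L, so no interpolation is assumed).
    """

    L: int = 129
    alpha: float | None = None
    S: float = DEFAULT_S
    omega_bar: float = OMEGA_BAR_1KX5
    per_step_average: bool = True

    def __post_init__(self) -> None:
        if self.L % 2 == 0 or not 3 <= self.L <= 147:
            raise ValueError(f"window length L must be odd and in [3, 147]; got {self.L}")
        if self.alpha is None:
            if self.L not in DEFAULT_ALPHA:
                raise ValueError(
                    f"no default total bend alpha for L={self.L}; pass alpha "
                    f"explicitly (defaults exist for L in {sorted(DEFAULT_ALPHA)})"
                )
            object.__setattr__(self, "alpha", DEFAULT_ALPHA[self.L])
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not self.S > 0:
            raise ValueError("S must be positive")
        if not 20.0 < self.omega_bar < 50.0:
            raise ValueError("omega_bar outside the plausible (20, 50) deg range")

    @property
    def half(self) -> int:
        """Offset from window start to the dyad (centre) base."""
        return (self.L - 1) // 2


@dataclass(frozen=True)
class TwistPhase:
    """Scaled step twists and cumulative dyad-phased twists for one window."""

    scaled_twists: np.ndarray  # degrees per step, length L-1
    cumulative: np.ndarray     # Omega_i at the centre of each step, degrees


@dataclass(frozen=True)
class WindowEnergy:
    """Deformation energies (per step if configured) and constraint forces."""

    E_bend: float
    E_shear: float
    F_b: float
    F_s: float

    @property
    def E_total(self) -> float:
        return self.E_bend + self.E_shear


@dataclass
class EnergyProfile:
    """Per-dyad-position energies along a sequence (0-based coordinates).

    ``bend[k]`` scores the window centred at sequence position
    ``start_offset + k``; windows containing ambiguous bases are flagged
    invalid (NaN values, ``valid`` False) rather than silently zeroed.
    """

    sequence_id: str
    start_offset: int
    bend: np.ndarray
    shear: np.ndarray
    total: np.ndarray
    valid: np.ndarray
    L: int

    def __len__(self) -> int:
        return len(self.bend)

    def centers(self) -> np.ndarray:
        return self.start_offset + np.arange(len(self.bend))

    def channel(self, name: str) -> np.ndarray:
        if name not in ("bend", "shear", "total"):
            raise ValueError(f"unknown energy channel {name!r}")
        return getattr(self, name)


# ---------------------------------------------------------------------------
# Core vectorised computation
# ---------------------------------------------------------------------------


def _phases_from_scaled(scaled: np.ndarray, half: int) -> np.ndarray:
    """Cumulative twist at the centre of each step, dyad-anchored.

    ``scaled`` has shape (n_windows, L-1); steps ``half:`` are downstream of
    the dyad (+1, +2, ...), steps ``:half`` upstream.  Step +-1 lies half a
    step from the dyad, so each step's own scaled twist contributes half,
    preceding steps contribute fully; upstream phases are negative
    (antisymmetric for palindromic twist profiles).
    """
    right = scaled[:, half:]
    omega_right = np.cumsum(right, axis=1) - right / 2.0
    left = scaled[:, :half][:, ::-1]
    omega_left = -(np.cumsum(left, axis=1) - left / 2.0)
    phases = np.empty_like(scaled)
    phases[:, half:] = omega_right
    phases[:, :half] = omega_left[:, ::-1]
    return phases


def _window_components(step_codes_2d: np.ndarray, geom: dict[str, np.ndarray],
                       config: EnergyModelConfig
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(E_bend, E_shear, F_b, F_s) for a batch of step-code windows."""
    n_steps = config.L - 1
    scale = (n_steps * config.omega_bar
             / geom["twist0"][step_codes_2d].sum(axis=1))
    scaled = geom["twist0"][step_codes_2d] * scale[:, None]
    phases = np.deg2rad(_phases_from_scaled(scaled, config.half))
    cos, sin = np.cos(phases), np.sin(phases)

    a0 = (geom["roll0"][step_codes_2d] * cos
          + geom["tilt0"][step_codes_2d] * sin).sum(axis=1)
    cb = (cos ** 2 / geom["k_roll"][step_codes_2d]
          + sin ** 2 / geom["k_tilt"][step_codes_2d]).sum(axis=1)
    f_b = (config.alpha - a0) / cb
    e_bend = (config.alpha - a0) ** 2 / (2.0 * cb)

    b0 = (geom["slide0"][step_codes_2d] * cos
          + geom["shift0"][step_codes_2d] * sin).sum(axis=1)
    cs = (cos ** 2 / geom["k_slide"][step_codes_2d]
          + sin ** 2 / geom["k_shift"][step_codes_2d]).sum(axis=1)
    f_s = (config.S - b0) / cs
    e_shear = (config.S - b0) ** 2 / (2.0 * cs)

    if config.per_step_average:
        e_bend = e_bend / n_steps
        e_shear = e_shear / n_steps
    return e_bend, e_shear, f_b, f_s


def _require_window(sequence: str, config: EnergyModelConfig) -> np.ndarray:
    codes = encode_sequence(sequence)
    if len(codes) != config.L:
        raise ValueError(f"window length {len(codes)} != configured L={config.L}")
    if (codes < 0).any():
        raise ValueError("window contains ambiguous (non-ACGT) bases")
    return codes[:-1] * 4 + codes[1:]


def twist_phase(window_sequence: str, params: ParamTable,
                config: EnergyModelConfig) -> TwistPhase:
    """Scaled equilibrium twists and cumulative phases for one window.

    The scaled twists sum exactly to ``(L-1) * omega_bar``.
    """
    steps = _require_window(window_sequence, config)
    geom = params.geometry_arrays()
    tw = geom["twist0"][steps]
    scaled = tw * ((config.L - 1) * config.omega_bar / tw.sum())
    cumulative = _phases_from_scaled(scaled[None, :], config.half)[0]
    return TwistPhase(scaled_twists=scaled, cumulative=cumulative)


def window_energy(window_sequence: str, params: ParamTable,
                  config: EnergyModelConfig) -> WindowEnergy:
    """Deformation energy of a single L-bp window centred on its dyad."""
    steps = _require_window(window_sequence, config)
    geom = params.geometry_arrays()
    e_bend, e_shear, f_b, f_s = _window_components(steps[None, :], geom, config)
    return WindowEnergy(E_bend=float(e_bend[0]), E_shear=float(e_shear[0]),
                        F_b=float(f_b[0]), F_s=float(f_s[0]))


def bending_energy(window_sequence: str, params: ParamTable,
                   config: EnergyModelConfig) -> tuple[float, float]:
    """(E_bend, F_b) for one window."""
    we = window_energy(window_sequence, params, config)
    return we.E_bend, we.F_b


def shearing_energy(window_sequence: str, params: ParamTable,
                    config: EnergyModelConfig) -> tuple[float, float]:
    """(E_shear, F_s) for one window."""
    we = window_energy(window_sequence, params, config)
    return we.E_shear, we.F_s


def energy_profile(sequence: str, params: ParamTable,
                   config: EnergyModelConfig | None = None,
                   sequence_id: str = "",
                   chunk: int = 8192) -> EnergyProfile:
    """Sliding-window energy profile (step 1 bp) along a sequence.

    The value at centre position ``c`` is the window energy of
    ``sequence[c - (L-1)/2 : c + (L-1)/2 + 1]``; a pure, context-free function
    of the window.  Windows containing ambiguous bases are flagged invalid.
    """
    config = config or EnergyModelConfig()
    codes = encode_sequence(sequence)
    n = len(codes)
    if n < config.L:
        warnings.warn(
            f"sequence {sequence_id or '<unnamed>'} shorter than window "
            f"({n} < {config.L}); empty profile"
        )
        empty = np.empty(0)
        return EnergyProfile(sequence_id, config.half, empty.copy(), empty.copy(),
                             empty.copy(), np.empty(0, dtype=bool), config.L)

    geom = params.geometry_arrays()
    n_win = n - config.L + 1
    ambiguous = codes < 0
    # window is valid iff no ambiguous base anywhere inside it
    bad_prefix = np.concatenate([[0], np.cumsum(ambiguous)])
    valid = (bad_prefix[config.L:] - bad_prefix[:-config.L]) == 0

    steps = np.where(ambiguous[:-1] | ambiguous[1:], 0,
                     codes[:-1] * 4 + codes[1:]).astype(np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(steps, config.L - 1)

    bend = np.full(n_win, np.nan)
    shear = np.full(n_win, np.nan)
    for lo in range(0, n_win, chunk):
        hi = min(lo + chunk, n_win)
        idx = np.nonzero(valid[lo:hi])[0]
        if len(idx) == 0:
            continue
        e_b, e_s, _, _ = _window_components(windows[lo + idx], geom, config)
        bend[lo + idx] = e_b
        shear[lo + idx] = e_s
    total = bend + shear
    return EnergyProfile(sequence_id, config.half, bend, shear, total,
                         valid, config.L)
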