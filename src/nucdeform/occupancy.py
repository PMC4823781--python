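"""Thermodynamic nucleosome occupancy from deformation-energy tracks.

Two models convert a per-start energy array into probabilities:

* **Grand-canonical hard-rod model** -- nucleosomes are rods of ``footprint``
  bp exchanging with a histone reservoir at fugacity ``tau``; a bound rod
  starting at *i* carries statistical weight ``tau * exp(-beta * E(i))`` and
  rods may not overlap.  The partition function over all non-overlapping
  configurations is computed exactly by forward/backward dynamic programming
  in log space, giving exact start probabilities.

* **Boltzmann model** -- start weights ``exp(-beta * E(i))`` normalised over
  all legal starts, with no steric exclusion; occupancy is the footprint
  window sum rescaled to a maximum of one.

Occupancy at position *j* is the probability of being covered by any
nucleosome, i.e. the sum of start probabilities over the footprint window
ending at *j*; dyad probability is the start probability re-centred by
``(footprint - 1) / 2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .energy import EnergyModelConfig, EnergyProfile, energy_profile
from .params import ParamTable


@dataclass(frozen=True)
class ThermoConfig:
    """Thermodynamic parameters of the occupancy layer.

    Defaults are the settings used for genome-scale occupancy fits
    (tau = 0.001, beta = 15, shear channel); dyad-probability work uses
    tau = 0.35, beta = 35 on the bend channel.
    """

    tau: float = 0.001
    beta: float = 15.0
    footprint: int = 147
    energy_channel: str = "shear"

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if not self.beta >= 0:
            raise ValueError("beta must be non-negative")
        if self.footprint < 1:
            raise ValueError("footprint must be a positive integer")
        if self.energy_channel not in ("bend", "shear", "total"):
            raise ValueError(f"unknown energy channel {self.energy_channel!r}")


@dataclass
class OccupancyProfile:
    """Start/dyad probabilities and occupancy over sequence coordinates."""

    sequence_id: str
    start_prob: np.ndarray
    dyad_prob: np.ndarray
    occupancy: np.ndarray
    partition_log: float
    footprint: int

    def __len__(self) -> int:
        return len(self.occupancy)


def _spread(p_start: np.ndarray, footprint: int, seq_len: int,
            sequence_id: str, partition_log: float) -> OccupancyProfile:
    start = np.zeros(seq_len)
    start[: len(p_start)] = p_start
    dyad = np.zeros(seq_len)
    dyad[(footprint - 1) // 2 : (footprint - 1) // 2 + len(p_start)] = p_start
    occupancy = np.convolve(p_start, np.ones(footprint))[:seq_len]
    return OccupancyProfile(sequence_id, start, dyad, occupancy,
                            partition_log, footprint)


def _empty(seq_len: int, footprint: int, sequence_id: str) -> OccupancyProfile:
    z = np.zeros(seq_len)
    return OccupancyProfile(sequence_id, z, z.copy(), z.copy(), 0.0, footprint)


def grand_canonical(energies: np.ndarray, config: ThermoConfig,
                    sequence_id: str = "") -> OccupancyProfile:
    """Exact hard-rod start probabilities by forward/backward recursion.

    ``energies[i]`` is the deformation energy of a nucleosome starting at
    position ``i`` (one entry per legal start; +inf marks invalid starts).
    All arithmetic is in log space, so arbitrarily large ``beta * E`` cannot
    overflow.
    """
    e = np.asarray(energies, dtype=float)
    a = config.footprint
    n_starts = len(e)
    if n_starts == 0:
        warnings.warn("footprint longer than sequence; all-zero occupancy")
        return _empty(0, a, sequence_id)
    seq_len = n_starts + a - 1

    with np.errstate(invalid="ignore"):
        lw = np.where(np.isfinite(e), np.log(config.tau) - config.beta * e,
                      -np.inf)

    # Zf[j]: log partition of the prefix [0, j); Zb[j]: of the suffix [j, N)
    zf = np.zeros(seq_len + 1)
    for j in range(1, seq_len + 1):
        z = zf[j - 1]
        if j >= a:
            z = np.logaddexp(z, zf[j - a] + lw[j - a])
        zf[j] = z
    zb = np.zeros(seq_len + 1)
    for j in range(seq_len - 1, -1, -1):
        z = zb[j + 1]
        if j <= seq_len - a:
            z = np.logaddexp(z, lw[j] + zb[j + a])
        zb[j] = z

    log_p = zf[:n_starts] + lw + zb[a : a + n_starts] - zf[seq_len]
    p = np.exp(log_p)
    return _spread(p, a, seq_len, sequence_id, float(zf[seq_len]))


def boltzmann(energies: np.ndarray, beta: float, footprint: int = 147,
              sequence_id: str = "") -> OccupancyProfile:
    """Independent-site Boltzmann weights, no steric exclusion.

    Start weights ``exp(-beta E)`` are normalised globally over the
    sequence's legal starts; occupancy (the footprint window sum) is rescaled
    so its maximum is one.
    """
    if not beta >= 0:
        raise ValueError("beta must be non-negative")
    e = np.asarray(energies, dtype=float)
    a = footprint
    n_starts = len(e)
    if n_starts == 0:
        warnings.warn("footprint longer than sequence; all-zero occupancy")
        return _empty(0, a, sequence_id)
    seq_len = n_starts + a - 1

    with np.errstate(invalid="ignore"):
        lw = np.where(np.isfinite(e), -beta * e, -np.inf)
    if not np.isfinite(lw).any():
        warnings.warn("no valid start positions; all-zero occupancy")
        return _empty(seq_len, a, sequence_id)
    log_z = logsumexp(lw)
    p = np.exp(lw - log_z)
    profile = _spread(p, a, seq_len, sequence_id, float(log_z))
    peak = profile.occupancy.max()
    if peak > 0:
        profile.occupancy = profile.occupancy / peak
    return profile


def start_energies(profile: EnergyProfile, footprint: int,
                   seq_len: int, channel: str) -> np.ndarray:
    """Per-start energy array for a nucleosome of ``footprint`` bp.

    A nucleosome starting at ``i`` has its dyad at ``i + (footprint-1)/2``;
    the energy is the profile value at that dyad.  Starts whose dyad has no
    valid profile value carry +inf.
    """
    values = profile.channel(channel)
    n_starts = seq_len - footprint + 1
    if n_starts <= 0:
        return np.empty(0)
    out = np.full(n_starts, np.inf)
    dyads = np.arange(n_starts) + (footprint - 1) // 2
    idx = dyads - profile.start_offset
    ok = (idx >= 0) & (idx < len(values))
    sel = idx[ok]
    vals = values[sel]
    usable = profile.valid[sel] & np.isfinite(vals)
    out_idx = np.nonzero(ok)[0][usable]
    out[out_idx] = vals[usable]
    return out


def occupancy_track(sequence: str, params: ParamTable,
                    energy_config: EnergyModelConfig | None = None,
                    thermo_config: ThermoConfig | None = None,
                    model: str = "grand_canonical",
                    sequence_id: str = "") -> OccupancyProfile:
    """End-to-end: sequence -> energy profile -> occupancy profile.

    Deterministic: identical inputs give bit-identical outputs.
    """
    energy_config = energy_config or EnergyModelConfig()
    thermo_config = thermo_config or ThermoConfig()
    if model not in ("grand_canonical", "boltzmann"):
        raise ValueError(f"unknown model {model!r}")

    profile = energy_profile(sequence, params, energy_config,
                             sequence_id=sequence_id)
    e = start_energies(profile, thermo_config.footprint, len(sequence),
                       thermo_config.energy_channel)
    if len(e) and not np.isfinite(e).any():
        warnings.warn(
            f"sequence {sequence_id or '<unnamed>'}: no valid windows; "
            f"empty occupancy profile"
        )
    if model == "grand_canonical":
        return grand_canonical(e, thermo_config, sequence_id=sequence_id)
    return boltzmann(e, thermo_config.beta, thermo_config.footprint,
                     sequence_id=sequence_id)
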