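"""Deterministic synthetic inputs, plus the packaged benchmark data.

Everything here is a pure function of its seed: synthetic sequences with
planted periodic dinucleotides (emulating the ~10-bp AA/TT/TA/AT vs
CC/GG/CG/GC rotational-positioning signal of real nucleosomal DNA),
Gaussian base-pair-step observation samples for parameter-recovery tests,
and the packaged benchmark.

The packaged benchmark is **synthetic**: ten DNA sequences carrying twenty
nucleosome positions whose rotational phasing is planted by construction
(dinucleotides with large positive equilibrium roll at phases where
``cos(Omega)`` is high, AA/TT at the opposite phase), mirroring the
structure of sequences used to assemble nucleosomes in vitro.  It ships as
FASTA + BED files with recorded checksums; nothing is fetched at run time.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import OMEGA_BAR_1KX5
from .params import (ParamTable, StepObservation, load_default_table)

#: Fixed seed of the packaged benchmark (never varied at run time).
BENCHMARK_SEED = 24133

_DATA_PKG = "nucdeform"
_FASTA_NAME = "invitro_benchmark_synthetic.fa"
_BED_NAME = "invitro_dyads_synthetic.bed"
_CHECKSUM_NAME = "checksums.json"


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic sequence with planted periodic dinucleotides."""

    seed: int
    length: int
    periodic_dinucs: tuple = ()  # (dinucleotide, period, phase) triples
    background_gc: float = 0.39  # yeast-like genomic GC

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("length must be >= 2")
        if not 0.0 <= self.background_gc <= 1.0:
            raise ValueError("background_gc must be in [0, 1]")
        for dinuc, period, phase in self.periodic_dinucs:
            if period <= 0:
                raise ValueError(f"period must be positive ({dinuc}: {period})")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.array(list("ACGT")), size=n, p=probs)


def synth_sequence(spec: SynthSpec) -> str:
    """i.i.d. background at the requested GC plus planted dinucleotides.

    Placements are applied in list order; a later placement overwrites any
    earlier one it overlaps (one summary warning reports the conflicts).
    """
    rng = np.random.default_rng(spec.seed)
    seq = _random_bases(rng, spec.length, spec.background_gc)
    planted = np.zeros(spec.length, dtype=bool)
    conflicts = 0
    for dinuc, period, phase in spec.periodic_dinucs:
        for pos in range(int(phase), spec.length - 1, int(period)):
            if planted[pos] or planted[pos + 1]:
                conflicts += 1
            seq[pos] = dinuc[0]
            seq[pos + 1] = dinuc[1]
            planted[pos:pos + 2] = True
    if conflicts:
        warnings.warn(f"{conflicts} overlapping placement(s); later wins")
    return "".join(seq)


def synth_step_observations(n: int, mean_vector, covariance, dinuc: str,
                            seed: int) -> list[StepObservation]:
    """Gaussian step sample with known generating moments.

    ``mean_vector`` and ``covariance`` are in shift/slide/rise/tilt/roll/twist
    order; the covariance must be symmetric positive definite.
    """
    mean = np.asarray(mean_vector, dtype=float)
    cov = np.asarray(covariance, dtype=float)
    if mean.shape != (6,) or cov.shape != (6, 6):
        raise ValueError("mean must be length 6 and covariance 6x6")
    if not np.allclose(cov, cov.T):
        raise ValueError("covariance must be symmetric")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 0:
        raise ValueError(f"covariance not positive definite (min eig {eigvals.min()})")
    rng = np.random.default_rng(seed)
    sample = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
    return [StepObservation(dinuc, *row, source_id=f"synth{i}")
            for i, row in enumerate(sample)]


# ---------------------------------------------------------------------------
# Synthetic in-vitro benchmark
# ---------------------------------------------------------------------------

_BENCH_IDS = [
    "pGUB_synth", "nuc601_synth", "fiveS_rDNA_A_synth", "fiveS_rDNA_B_synth",
    "chickenBG_synth", "mmtvA_synth", "litAFN_synth", "seaUrchin5S_synth",
    "promoterX_synth", "telomericY_synth",
]

#: Planting sets: high positive equilibrium roll vs stiff/low roll classes.
_HIGH_ROLL = ("CA", "CG", "TG")
_LOW_ROLL = ("AA", "TT")


def _plant_rotational_signal(seq: np.ndarray, dyad: int,
                             rng: np.random.Generator,
                             reach: int = 60, threshold: float = 0.6) -> None:
    """Impose a dyad-phased roll signal around ``dyad`` in place.

    Steps whose approximate phase ``(|k| - 1/2) * omega_bar`` has cosine above
    the threshold receive a high-roll dinucleotide, those below the negative
    threshold a low-roll one -- the in-phase/out-of-phase ~10-bp pattern of
    nucleosome-forming sequences.
    """
    for k in range(-reach, reach + 1):
        if k == 0:
            continue
        phase = np.deg2rad((abs(k) - 0.5) * OMEGA_BAR_1KX5)
        c = np.cos(phase)
        if c > threshold:
            dinuc = rng.choice(_HIGH_ROLL)
        elif c < -threshold:
            dinuc = rng.choice(_LOW_ROLL)
        else:
            continue
        base = dyad + k - 1 if k > 0 else dyad + k
        if 0 <= base < len(seq) - 1:
            seq[base] = dinuc[0]
            seq[base + 1] = dinuc[1]


def build_benchmark(seed: int = BENCHMARK_SEED, n_sequences: int = 10,
                    length: int = 380, dyad_offsets: tuple = (95, 285),
                    background_gc: float = 0.39
                    ) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate the synthetic in-vitro benchmark: sequences + dyad list.

    Ten sequences, two planted nucleosome positions each (twenty dyads),
    lengths comparable to in-vitro reconstitution fragments.  Returns the
    sequence dict and a BED-style DataFrame of 1-bp dyad intervals.
    """
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    rows = []
    for i in range(n_sequences):
        name = _BENCH_IDS[i] if i < len(_BENCH_IDS) else f"bench{i}_synth"
        seq = _random_bases(rng, length, background_gc)
        for j, dyad in enumerate(dyad_offsets):
            _plant_rotational_signal(seq, int(dyad), rng)
            rows.append((name, int(dyad), int(dyad) + 1, f"dyad_{j + 1}"))
        sequences[name] = "".join(seq)
    dyads = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return sequences, dyads


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def packaged_benchmark(data_dir: Path | None = None
                       ) -> tuple[dict[str, str], pd.DataFrame, ParamTable]:
    """The shipped benchmark: 10 sequences, 20 dyads, default ParamTable.

    Files are integrity-checked against recorded SHA-256 checksums; a
    mismatch raises rather than returning silently corrupted fixtures.
    ``data_dir`` overrides the packaged data location (testing hook).
    """
    from .io_formats import read_bed, read_fasta  # local import: cycle-free

    if data_dir is None:
        with resources.as_file(resources.files(_DATA_PKG) / "data") as p:
            return packaged_benchmark(Path(p))
    checksums = json.loads((data_dir / _CHECKSUM_NAME).read_text())
    for fname in (_FASTA_NAME, _BED_NAME):
        digest = _sha256(data_dir / fname)
        if digest != checksums[fname]:
            raise ValueError(
                f"packaged fixture {fname} failed its integrity check "
                f"({digest} != {checksums[fname]})"
            )
    sequences = read_fasta(data_dir / _FASTA_NAME)
    dyads = read_bed(data_dir / _BED_NAME)
    table = load_default_table()
    return sequences, dyads, table
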