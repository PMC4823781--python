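"""Dinucleotide stiffness parameters estimated from base-pair-step observations.

A base-pair step is described by six rigid-body degrees of freedom (shift,
slide, rise, tilt, roll, twist; Cambridge convention).  From a sample of steps
observed in protein-DNA crystal structures this module estimates, per
dinucleotide:

* equilibrium geometry -- the mean step parameters in the absence of stress;
* harmonic force constants -- diagonal entries of the inverted 6x6 covariance
  matrix of deviations from the equilibrium values (a stiffness matrix).

Two conventions matter throughout.  First, each *physical* step is counted
exactly once: re-reading a step on the complementary strand flips the signs of
tilt and shift, so double counting would inflate their variances (roughly
four-fold when the per-strand mean dominates the spread) and corrupt the force
constants.  Second, complementary dinucleotides share roll/twist/slide
equilibria and all force constants, while their equilibrium tilt and shift
differ only in sign; for self-complementary dinucleotides (AT, TA, CG, GC)
equilibrium tilt and shift are identically zero.  These symmetries make the
deformation energies strand-invariant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)
SELF_COMPLEMENTARY = ("AT", "TA", "CG", "GC")

#: Order of the six geometric step parameters used everywhere in this module.
GEOM_FIELDS = ("shift", "slide", "rise", "tilt", "roll", "twist")
_I_SHIFT, _I_SLIDE, _I_RISE, _I_TILT, _I_ROLL, _I_TWIST = range(6)

# Sign changes applied to a step vector when the step is re-expressed on the
# complementary strand: tilt and shift change sign, the rest are invariant.
STRAND_FLIP = np.array([-1.0, 1.0, 1.0, -1.0, 1.0, 1.0])

#: Condition-number limit above which a step covariance is refused.
COND_LIMIT = 1e10


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(dinuc: str) -> str:
    """Lexicographically smaller of a dinucleotide and its reverse complement.

    Used as the representative of the complement-equivalence class; there are
    ten such classes over the sixteen dinucleotides.
    """
    return min(dinuc, revcomp(dinuc))


CANONICAL_CLASSES = tuple(sorted({canonical(d) for d in DINUCLEOTIDES}))


@dataclass(frozen=True)
class StepObservation:
    """One observed base-pair step on the reference strand of a structure."""

    dinucleotide: str
    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.dinucleotide) != 2 or any(
            b not in BASES for b in self.dinucleotide
        ):
            raise ValueError(f"not an ACGT dinucleotide: {self.dinucleotide!r}")
        if not all(map(math.isfinite, self.vector())):
            raise ValueError(f"non-finite step parameters for {self.dinucleotide}")

    def vector(self) -> np.ndarray:
        """The six geometric parameters in :data:`GEOM_FIELDS` order."""
        return np.array(
            [self.shift, self.slide, self.rise, self.tilt, self.roll, self.twist]
        )


@dataclass(frozen=True)
class DinucParams:
    """Equilibrium geometry and force constants for one dinucleotide.

    Angles in degrees, translations in Angstrom; force constants in kT/deg^2
    and kT/A^2 (the thermodynamic layer's beta absorbs any global scale).
    """

    dinucleotide: str
    roll0: float
    tilt0: float
    twist0: float
    slide0: float
    shift0: float
    k_roll: float
    k_tilt: float
    k_slide: float
    k_shift: float
    n_obs: int = 0

    def __post_init__(self) -> None:
        for name in ("k_roll", "k_tilt", "k_slide", "k_shift"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive "
                                 f"({self.dinucleotide}: {getattr(self, name)})")
        if self.dinucleotide in SELF_COMPLEMENTARY and (
            self.tilt0 != 0.0 or self.shift0 != 0.0
        ):
            raise ValueError(
                f"self-complementary {self.dinucleotide} must have tilt0=shift0=0"
            )


_TSV_COLUMNS = [
    "dinuc", "roll0", "tilt0", "twist0", "slide0", "shift0",
    "k_roll", "k_tilt", "k_slide", "k_shift", "n_obs",
]


class ParamTable:
    """Complete parameter set over all sixteen dinucleotides.

    Enforces complement symmetry: for a dinucleotide ``d`` and its reverse
    complement ``d'``, roll0/twist0/slide0 and the four force constants agree,
    while ``tilt0(d') = -tilt0(d)`` and ``shift0(d') = -shift0(d)``.
    """

    def __init__(self, entries: Mapping[str, DinucParams], provenance: str = ""):
        self.entries = dict(entries)
        self.provenance = provenance
        self.validate()

    def __getitem__(self, dinuc: str) -> DinucParams:
        return self.entries[dinuc]

    def validate(self, atol: float = 1e-9) -> None:
        missing = [d for d in DINUCLEOTIDES if d not in self.entries]
        if missing:
            raise ValueError(f"ParamTable incomplete; missing {missing}")
        problems = []
        for d in DINUCLEOTIDES:
            p, q = self.entries[d], self.entries[revcomp(d)]
            for name in ("roll0", "twist0", "slide0",
                         "k_roll", "k_tilt", "k_slide", "k_shift"):
                if abs(getattr(p, name) - getattr(q, name)) > atol:
                    problems.append(f"{name}({d}) != {name}({revcomp(d)})")
            for name in ("tilt0", "shift0"):
                if abs(getattr(p, name) + getattr(q, name)) > atol:
                    problems.append(f"{name}({d}) != -{name}({revcomp(d)})")
        if problems:
            raise ValueError("complement symmetry violated: " + "; ".join(problems))

    # -- array views used by the energy layer ------------------------------

    def geometry_arrays(self) -> dict[str, np.ndarray]:
        """Per-dinucleotide arrays indexed by code ``4*b1 + b2`` (A,C,G,T=0..3)."""
        out = {name: np.empty(16) for name in
               ("roll0", "tilt0", "twist0", "slide0", "shift0",
                "k_roll", "k_tilt", "k_slide", "k_shift")}
        for code, d in enumerate(DINUCLEOTIDES):
            p = self.entries[d]
            for name in out:
                out[name][code] = getattr(p, name)
        return out

    # -- TSV round trip -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "dinuc": d,
                **{c: getattr(self.entries[d], c if c != "dinuc" else "dinucleotide")
                   for c in _TSV_COLUMNS[1:]},
            }
            for d in DINUCLEOTIDES
        ]
        return pd.DataFrame(rows, columns=_TSV_COLUMNS)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "") -> "ParamTable":
        entries = {}
        for _, row in frame.iterrows():
            entries[row["dinuc"]] = DinucParams(
                dinucleotide=row["dinuc"],
                roll0=float(row["roll0"]), tilt0=float(row["tilt0"]),
                twist0=float(row["twist0"]), slide0=float(row["slide0"]),
                shift0=float(row["shift0"]),
                k_roll=float(row["k_roll"]), k_tilt=float(row["k_tilt"]),
                k_slide=float(row["k_slide"]), k_shift=float(row["k_shift"]),
                n_obs=int(row["n_obs"]),
            )
        return cls(entries, provenance=provenance)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ParamTable":
        frame = pd.read_csv(path, sep="\t")
        return cls.from_frame(frame, provenance=str(path))


def load_default_table() -> ParamTable:
    """Packaged default parameter table.

    The shipped table is synthetic: it was generated once from a synthetic
    step-observation ensemble whose means and spreads follow B-DNA
    crystallographic survey averages (flexible pyrimidine-purine steps, stiff
    AT-rich steps, ~34.5 deg mean twist).  It satisfies every ParamTable
    invariant and provides a realistic default where no user-estimated table
    is supplied.
    """
    ref = resources.files("nucdeform") / "data" / "dinuc_params_synthetic_default.tsv"
    with resources.as_file(ref) as path:
        table = ParamTable.read_tsv(path)
    table.provenance = "packaged synthetic default (B-DNA survey calibrated)"
    return table


# ---------------------------------------------------------------------------
# Estimation pipeline
# ---------------------------------------------------------------------------


def load_step_observations(path: str | Path) -> list[StepObservation]:
    """Parse a whitespace-delimited step table.

    One step per row: dinucleotide, shift, slide, rise, tilt, roll, twist and
    an optional trailing source identifier; ``#`` lines are comments.  Rows
    whose dinucleotide contains non-ACGT characters are skipped (a single
    summary warning reports the count); each row is assumed to describe a
    distinct physical step on the reference strand.
    """
    observations: list[StepObservation] = []
    skipped = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            fields = text.split()
            if len(fields) < 7:
                raise ValueError(
                    f"{path}:{lineno}: expected dinucleotide + 6 numeric columns, "
                    f"got {len(fields)} fields"
                )
            dinuc = fields[0].upper()
            if len(dinuc) != 2 or any(b not in BASES for b in dinuc):
                skipped += 1
                continue
            try:
                values = [float(x) for x in fields[1:7]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
            source = fields[7] if len(fields) > 7 else ""
            observations.append(StepObservation(dinuc, *values, source_id=source))
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} row(s) with non-ACGT dinucleotides")
    return observations


def write_step_observations(observations: Iterable[StepObservation],
                            path: str | Path) -> None:
    """Inverse of :func:`load_step_observations` (12 significant digits)."""
    with open(path, "w") as handle:
        handle.write("# dinuc shift slide rise tilt roll twist source\n")
        for o in observations:
            vals = " ".join(f"{v:.12g}" for v in o.vector())
            handle.write(f"{o.dinucleotide} {vals} {o.source_id}\n".rstrip() + "\n")


def filter_outliers(observations: Sequence[StepObservation],
                    n_sd: float = 2.0) -> list[StepObservation]:
    """Drop dramatically distorted steps in a single, non-iterative pass.

    An observation is removed iff at least one of its six parameters deviates
    from the mean of its dinucleotide type by more than ``n_sd`` sample
    standard deviations, with means and SDs computed on the unfiltered input.
    Types with fewer than two observations are kept unfiltered (warning).
    """
    if not n_sd > 0:
        raise ValueError("n_sd must be positive")
    groups: dict[str, list[int]] = {}
    for idx, o in enumerate(observations):
        groups.setdefault(o.dinucleotide, []).append(idx)

    keep = np.ones(len(observations), dtype=bool)
    small = []
    for dinuc, idxs in groups.items():
        if len(idxs) < 2:
            small.append(dinuc)
            continue
        X = np.array([observations[i].vector() for i in idxs])
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore"):
            bad = np.any(np.abs(X - mean) > n_sd * sd, axis=1)
        for i, b in zip(idxs, bad):
            if b:
                keep[i] = False
    if small:
        warnings.warn(
            f"dinucleotide type(s) with <2 observations kept unfiltered: {small}"
        )
    return [o for o, k in zip(observations, keep) if k]


def _class_members(observations: Sequence[StepObservation]
                   ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Split observations by canonical class into (own-strand, partner) arrays."""
    raw: dict[str, list[np.ndarray]] = {d: [] for d in DINUCLEOTIDES}
    for o in observations:
        raw[o.dinucleotide].append(o.vector())
    out = {}
    for rep in CANONICAL_CLASSES:
        partner = revcomp(rep)
        own = np.array(raw[rep]) if raw[rep] else np.empty((0, 6))
        if partner == rep:
            other = np.empty((0, 6))
        else:
            other = np.array(raw[partner]) if raw[partner] else np.empty((0, 6))
        out[rep] = (own, other)
    return out


def estimate_equilibrium(observations: Sequence[StepObservation]
                         ) -> dict[str, dict[str, float]]:
    """Per-dinucleotide equilibrium structural parameters.

    roll0/twist0/slide0 are means over the dinucleotide pooled with its
    reverse complement (the complement's tilt and shift sign-flipped before
    pooling; both are invariant under that flip so pooling is exact).  tilt0
    and shift0 are computed per strand and then antisymmetrized,
    ``tilt0(d) = (mean_tilt(d) - mean_tilt(d'))/2``, so complementary values
    differ only in sign; self-complementary dinucleotides get zero.

    Returns a mapping over all sixteen dinucleotides.
    """
    members = _class_members(observations)
    empty = [rep for rep, (own, other) in members.items()
             if len(own) + len(other) == 0]
    if empty:
        raise ValueError(f"no observations for dinucleotide class(es): {empty}")

    result: dict[str, dict[str, float]] = {}
    for rep, (own, other) in members.items():
        pooled = np.vstack([own, other * STRAND_FLIP])
        mean = pooled.mean(axis=0)
        if rep in SELF_COMPLEMENTARY:
            tilt0 = shift0 = 0.0
        elif len(own) and len(other):
            tilt0 = (own[:, _I_TILT].mean() - other[:, _I_TILT].mean()) / 2.0
            shift0 = (own[:, _I_SHIFT].mean() - other[:, _I_SHIFT].mean()) / 2.0
        else:
            # single-strand class: the frame-mapped mean is the only estimate
            tilt0 = float(mean[_I_TILT])
            shift0 = float(mean[_I_SHIFT])
        eq = {
            "roll0": float(mean[_I_ROLL]),
            "twist0": float(mean[_I_TWIST]),
            "slide0": float(mean[_I_SLIDE]),
            "rise0": float(mean[_I_RISE]),
            "tilt0": float(tilt0),
            "shift0": float(shift0),
        }
        result[rep] = eq
        partner = revcomp(rep)
        if partner != rep:
            result[partner] = {**eq, "tilt0": -tilt0, "shift0": -shift0}
    return result


def estimate_force_constants(observations: Sequence[StepObservation],
                             min_obs: int = 8) -> dict[str, dict[str, float]]:
    """Force constants from the inverted 6x6 step covariance, per class.

    For each complement-equivalence class the observations (each physical step
    counted exactly once; partner-strand records are re-expressed in the
    representative frame with tilt/shift negated) are pooled, the sample
    covariance of deviations about the pooled means is formed over all six
    parameters, inverted, and the diagonal entries for roll, tilt, slide and
    shift are reported.  Rise takes part in the inversion but its stiffness is
    discarded (it enters no energy term).  Force constants are shared between
    complementary dinucleotides.
    """
    members = _class_members(observations)
    result: dict[str, dict[str, float]] = {}
    for rep, (own, other) in members.items():
        pooled = np.vstack([own, other * STRAND_FLIP])
        n = len(pooled)
        if n < min_obs:
            raise ValueError(
                f"class {rep}: {n} observations < {min_obs} needed for a 6x6 "
                f"covariance"
            )
        cov = np.cov(pooled, rowvar=False, ddof=1)
        cond = np.linalg.cond(cov)
        if not np.isfinite(cond) or cond > COND_LIMIT:
            raise np.linalg.LinAlgError(
                f"class {rep}: step covariance ill-conditioned "
                f"(condition number {cond:.3e} > {COND_LIMIT:.0e})"
            )
        stiffness = np.linalg.inv(cov)
        fc = {
            "k_roll": float(stiffness[_I_ROLL, _I_ROLL]),
            "k_tilt": float(stiffness[_I_TILT, _I_TILT]),
            "k_slide": float(stiffness[_I_SLIDE, _I_SLIDE]),
            "k_shift": float(stiffness[_I_SHIFT, _I_SHIFT]),
            "n_obs": n,
        }
        result[rep] = fc
        partner = revcomp(rep)
        if partner != rep:
            result[partner] = dict(fc)
    return result


def build_param_table(equilibrium: Mapping[str, Mapping[str, float]],
                      force_constants: Mapping[str, Mapping[str, float]],
                      provenance: str = "estimated") -> ParamTable:
    """Assemble and validate a :class:`ParamTable` from the two estimates."""
    missing = [d for d in DINUCLEOTIDES
               if d not in equilibrium or d not in force_constants]
    if missing:
        raise ValueError(f"incomplete estimates; missing dinucleotides {missing}")
    entries = {}
    for d in DINUCLEOTIDES:
        eq, fc = equilibrium[d], force_constants[d]
        entries[d] = DinucParams(
            dinucleotide=d,
            roll0=eq["roll0"], tilt0=eq["tilt0"], twist0=eq["twist0"],
            slide0=eq["slide0"], shift0=eq["shift0"],
            k_roll=fc["k_roll"], k_tilt=fc["k_tilt"],
            k_slide=fc["k_slide"], k_shift=fc["k_shift"],
            n_obs=int(fc.get("n_obs", 0)),
        )
    return ParamTable(entries, provenance=provenance)


def estimate_parameters(observations: Sequence[StepObservation],
                        n_sd: float = 2.0,
                        provenance: str = "estimated") -> ParamTable:
    """Full pipeline: outlier filter -> equilibria -> force constants -> table."""
    filtered = filter_outliers(observations, n_sd=n_sd)
    eq = estimate_equilibrium(filtered)
    fc = estimate_force_constants(filtered)
    return build_param_table(eq, fc, provenance=provenance)
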