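"""Regenerate the packaged data files (maintenance; run from repo root).

Writes the synthetic default dinucleotide parameter table, the synthetic
in-vitro benchmark (FASTA + BED), and their SHA-256 checksums into
``src/nucdeform/data/``.  All outputs are deterministic.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd  # noqa: E402

from nucdeform.fixtures import BENCHMARK_SEED, build_benchmark  # noqa: E402
from nucdeform.io_formats import write_bed, write_fasta  # noqa: E402
from nucdeform.params import ParamTable, revcomp  # noqa: E402

DATA = ROOT / "src" / "nucdeform" / "data"

# Synthetic default parameters per complement-equivalence class, calibrated to
# B-DNA crystallographic survey averages: flexible pyrimidine-purine steps
# (CA/TG, TA, CG) with high positive roll and soft constants; stiff AT-rich
# steps; mean twist near the 1kx5 average.  Angles deg, translations Angstrom,
# force constants kT/deg^2 and kT/A^2.
CLASS_PARAMS = {
    # dinuc: roll0, tilt0, twist0, slide0, shift0, k_roll, k_tilt, k_slide, k_shift, n_obs
    "AA": (0.5, -1.5, 35.3, -0.10, -0.05, 0.045, 0.080, 3.0, 4.5, 1800),
    "AC": (0.6, -0.2, 32.0, -0.60, 0.10, 0.050, 0.090, 3.5, 5.0, 1200),
    "AG": (4.0, -1.6, 31.5, -0.30, 0.10, 0.040, 0.075, 2.8, 4.2, 1100),
    "AT": (0.9, 0.0, 30.5, -0.70, 0.00, 0.060, 0.100, 4.0, 5.5, 900),
    "CA": (5.3, 0.4, 35.0, 1.30, 0.10, 0.020, 0.050, 1.5, 3.0, 1300),
    "CC": (4.3, 0.1, 33.2, 0.50, 0.05, 0.035, 0.070, 2.2, 4.0, 1000),
    "CG": (5.5, 0.0, 34.0, 0.70, 0.00, 0.020, 0.050, 1.4, 3.0, 800),
    "GA": (1.7, -1.3, 37.0, -0.10, -0.10, 0.035, 0.070, 2.5, 4.0, 1150),
    "GC": (0.1, 0.0, 37.5, 0.40, 0.00, 0.030, 0.060, 2.0, 3.5, 950),
    "TA": (4.0, 0.0, 38.0, 0.10, 0.00, 0.018, 0.045, 1.3, 2.8, 700),
}

COLUMNS = ["dinuc", "roll0", "tilt0", "twist0", "slide0", "shift0",
           "k_roll", "k_tilt", "k_slide", "k_shift", "n_obs"]


def build_default_table() -> ParamTable:
    rows = []
    for rep, vals in CLASS_PARAMS.items():
        roll0, tilt0, twist0, slide0, shift0, kr, kt, ks, ksh, n = vals
        rows.append([rep, roll0, tilt0, twist0, slide0, shift0, kr, kt, ks, ksh, n])
        partner = revcomp(rep)
        if partner != rep:
            rows.append([partner, roll0, -tilt0, twist0, slide0, -shift0,
                         kr, kt, ks, ksh, n])
    frame = pd.DataFrame(rows, columns=COLUMNS).sort_values("dinuc")
    return ParamTable.from_frame(frame, provenance="synthetic default")


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)

    table = build_default_table()
    table.write_tsv(DATA / "dinuc_params_synthetic_default.tsv")

    sequences, dyads = build_benchmark(seed=BENCHMARK_SEED)
    write_fasta(sequences, DATA / "invitro_benchmark_synthetic.fa")
    write_bed(dyads, DATA / "invitro_dyads_synthetic.bed")

    checksums = {
        name: hashlib.sha256((DATA / name).read_bytes()).hexdigest()
        for name in ("invitro_benchmark_synthetic.fa",
                     "invitro_dyads_synthetic.bed")
    }
    (DATA / "checksums.json").write_text(json.dumps(checksums, indent=2) + "\n")
    print(f"wrote {len(list(DATA.iterdir()))} files to {DATA}")


if __name__ == "__main__":
    main()
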