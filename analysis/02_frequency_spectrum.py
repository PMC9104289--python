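#!/usr/bin/env python
"""Build the frequency database for the sequenced cohort and tabulate its
allele-frequency spectrum: impact x tier x class counts and per-class
singleton fractions."""

import subprocess
import sys
from pathlib import Path

import pandas as pd

from cohortvar import frequency_db as fq
from cohortvar import variant_io

ROOT = Path(__file__).resolve().parents[1]
SIM_DIR = ROOT / "scratch" / "simulated"


def main() -> None:
    if not (SIM_DIR / "cohort_a.vcf").exists():
        subprocess.run([sys.executable, str(ROOT / "analysis" / "01_simulate.py")],
                       check=True)
    sites = variant_io.read_small_variants(SIM_DIR / "cohort_a.vcf", "a")
    variant_io.write_frequency_vcf(sites, "a", SIM_DIR / "frequency_a.vcf")

    table = fq.spectrum_table(sites, "a")
    out = ROOT / "results" / "02_spectrum.tsv"
    out.write_text(table.to_long_tsv())

    frac = fq.singleton_fraction_by_class(sites, "a")
    frac_out = ROOT / "results" / "02_singleton_fractions.tsv"
    pd.Series(frac, name="singleton_fraction").rename_axis("variant_class").to_csv(
        frac_out, sep="\t"
    )
    print(f"{table.total} sites; impact marginals:\n{table.marginal('impact')}")
    print(f"singleton fractions: {frac}")
    print(f"-> {out} and {frac_out}")


if __name__ == "__main__":
    main()
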