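#!/usr/bin/env python
"""Compute the ion m/z assignments used throughout the lipid imaging.

Tabulates the monoisotopic m/z of the species the SIMS and MALDI analyses
annotate: the lithiated endocannabinoids and their deuterated internal
standards, the fatty-acid carboxylates, the phosphocholine fragment cation
and the cholesterol dehydration fragment.

Run:  python analysis/05_mass_assignments.py
"""

from pathlib import Path

import pandas as pd

from leechmsi import masscalc as mc

ROOT = Path(__file__).resolve().parents[1]

SPECIES = [
    ("2-AG", "C23H38O4", "M+Li"),
    ("2-AGd8", "C23H30[2H]8O4", "M+Li"),
    ("AEA", "C22H37NO2", "M+Li"),
    ("AEAd8", "C22H29[2H]8NO2", "M+Li"),
    ("oleic acid", "C18H34O2", "M-H"),
    ("stearic acid", "C18H36O2", "M-H"),
    ("phosphocholine", "C5H15NO4P", "preformed_cation"),
    ("cholesterol - H2O", "C27H46O", "M+H-H2O"),
]


def main() -> None:
    rows = []
    for name, formula, adduct in SPECIES:
        mz = mc.adduct_mz(formula, adduct)
        rows.append({"species": name, "formula": formula, "adduct": adduct, "mz": round(mz, 4)})
        print(f"{name:18s} {formula:16s} [{adduct}] -> m/z {mz:.4f}")
    out = ROOT / "results" / "ion_assignments.csv"
    out.parent.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
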