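"""Regenerate the bundled synthetic whole-blood coefficient table.

The table is a smooth analytic approximation to published whole-blood
absorption and scattering spectra in the visible band, not a copy of any
published dataset: mu_a curves are sums of Gaussians placed at the known
oxyhaemoglobin peaks (542, 576 nm) and the deoxyhaemoglobin peak (555 nm),
scaled to magnitudes implied by molar extinction at a total haemoglobin
concentration of 150 g/L (64500 g/mol); mu_s follows a smooth power law.
The curves reproduce the qualitative features the forward model needs
(sO2-dependent contrast strongest near 550-585 nm, isosbestic-like
crossings, monotone scattering) and nothing downstream depends on their
exact values -- exact-number tests use small toy tables.

Run from the repository root:  python scripts/make_coefficient_table.py
"""

from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parents[1] / "src" / "dslox" / "data" / "hemoglobin_synthetic.csv"

HEADER = """\
# Synthetic whole-blood optical coefficient table (1/mm), 515-635 nm.
# Analytic approximation to published whole-blood spectra; constructed by
# scripts/make_coefficient_table.py and bundled as package data.  Peaks:
# HbO2 542/576 nm, Hb 555 nm; magnitudes from molar extinction at 150 g/L
# total haemoglobin; mu_s ~ smooth power law around 560 nm.  Not a copy of
# any published table; do not use for quantitative work on real data.
# columns: wavelength_nm, mu_a_hb, mu_s_hb, mu_a_hbo2, mu_s_hbo2
"""


def gauss(lam, centre, width):
    return np.exp(-0.5 * ((lam - centre) / width) ** 2)


def build(lam):
    # deoxygenated whole blood: single broad alpha band + red-tail decay
    mu_a_hb = 26.0 * gauss(lam, 555.0, 24.0) + 8.0 * np.exp(-(lam - 515.0) / 80.0) + 0.3
    # oxygenated whole blood: twin alpha/beta bands, steep fall past 590 nm
    mu_a_hbo2 = (
        24.0 * gauss(lam, 542.0, 11.0)
        + 26.0 * gauss(lam, 576.0, 9.0)
        + 6.0 * np.exp(-(lam - 515.0) / 45.0)
        + 0.3
    )
    mu_s_hb = 85.0 * (lam / 560.0) ** -1.2
    mu_s_hbo2 = 92.0 * (lam / 560.0) ** -1.2
    return mu_a_hb, mu_s_hb, mu_a_hbo2, mu_s_hbo2


def main():
    lam = np.arange(515.0, 635.0 + 0.5, 1.0)
    cols = build(lam)
    data = np.column_stack([lam, *cols])
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with OUT.open("w") as fh:
        fh.write(HEADER)
        for row in data:
            fh.write(",".join(f"{v:.4f}" for v in row) + "\n")
    print(f"wrote {OUT} ({data.shape[0]} rows)")


if __name__ == "__main__":
    main()
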