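"""Assign oligomeric states to the SEC-MALS peak tables.

Maps each peak's weight-average molecular mass to the nearest integer
multiple of the construct's monomer mass and writes the assignment tables.
"""

from pathlib import Path

from bundlestab.oligomers import assign_peaks
from bundlestab.synthetic_data import DEFAULT_MONOMER_KDA, DEFAULT_PEAKS

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    for sample, peaks in DEFAULT_PEAKS.items():
        monomer = DEFAULT_MONOMER_KDA[sample]
        assignments, warnings = assign_peaks(peaks, monomer)
        lines = ["peak_id\tmw_kda\toligomer\tmass_fraction_pct\tresidual"]
        print(f"\n{sample} (monomer {monomer} kDa):")
        for a in assignments:
            lines.append(f"{a.peak_id}\t{a.mw}\t{a.oligomeric_number}\t"
                         f"{a.mass_fraction}\t{a.residual:.3f}")
            print(f"  peak {a.peak_id:<4} {a.mw:6.1f} kDa -> "
                  f"{a.oligomeric_number}-mer ({a.mass_fraction}% of mass)")
        for w in warnings:
            print(f"  warning: {w}")
        (OUT / f"04_oligomers_{sample}.tsv").write_text(
            "\n".join(lines) + "\n")


if __name__ == "__main__":
    main()
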