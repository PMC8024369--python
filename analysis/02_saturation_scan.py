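"""In-silico saturation mutagenesis and stability ranking.

Enumerates all substitutions at the buried hydrophilic sites, scores each
construct with the synthetic replicate-trajectory panel, applies the
post-scan filters and writes the ranked candidate table.
"""

from pathlib import Path

import numpy as np

from bundlestab.pipeline import run_study

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    report = run_study({"stages": ["sasa", "scan"]}, OUT / "02_scan")
    print(f"buried sites: {report.buried_sites}")
    print("rank  label        mean_rmsd  delta_vs_wt")
    for row in report.ranking:
        print(f"{row['rank']:>4}  {row['label']:<12} "
              f"{row['mean_rmsd']:>8.3f}  {row['delta_vs_wt']:>+10.3f}")


if __name__ == "__main__":
    main()
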