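#!/usr/bin/env python
"""Sensitivity of the simvastatin-vicagrel interaction to the CES1/CES2 Ki."""

import argparse
from pathlib import Path

from vicasim import scenarios as sc
from vicasim.parameters_config import default_fixture


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n-per-axis", type=int, default=4)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    registry = default_fixture()
    grid = sc.run_ki_sensitivity(registry, n_per_axis=args.n_per_axis)
    outdir = args.out / "ki_sensitivity"
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "ki_grid.csv"
    grid.to_csv(path, index=False)
    print(grid.to_string(index=False))
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
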