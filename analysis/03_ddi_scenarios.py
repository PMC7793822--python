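#!/usr/bin/env python
"""Drug-interaction scenarios: omeprazole (MBI on CYP2C19) against both
prodrugs, and simvastatin (reversible CES1/CES2 inhibition) against vicagrel."""

import argparse
from pathlib import Path

from vicasim import scenarios as sc
from vicasim.parameters_config import default_fixture

PAIRS = (
    ("omeprazole", "vicagrel"),
    ("omeprazole", "clopidogrel"),
    ("simvastatin", "vicagrel"),
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=None)
    parser.add_argument("--n-subjects", type=int, default=None)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    registry = default_fixture()
    for perpetrator, victim in PAIRS:
        result = sc.run_ddi_scenario(
            perpetrator, victim, registry,
            n_subjects=args.n_subjects, seed=args.seed,
        )
        outdir = args.out / result.name
        result.write(outdir)
        ratio = result.extras["amh4_auc_first_ratio_without_over_with"]
        print(f"{result.name}: AM-H4 AUC ratio (without/with) "
              f"{ratio:.3f} -> {outdir}")


if __name__ == "__main__":
    main()
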