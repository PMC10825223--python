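"""Stem-loop reporter screen on simulated editors.

Runs the reporter preset: three editors (a precise and a broad C-to-U
editor, a precise A-to-I editor) tethered to the 12x MS2 reporter in two
replicates each, plus a dual C-to-U/A-to-I pair on the alternating 4-loop
construct.  Reports per-position editing profiles, spillover into the CDS,
and on/off-target signal-to-noise, and writes everything to results/.
"""

import argparse

from rbekit import RunConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed, outdir=args.outdir)
    res = run_pipeline("reporter", cfg)

    onoff = res["onoff"].groupby("enzyme")["ratio"].mean()
    spill = res["spillover"].groupby("enzyme")["spillover_index"].mean()
    print("Mean on/off-target ratio per enzyme:")
    print(onoff.to_string(float_format="%.1f"))
    print("\nMean spillover index (fraction of edits on the CDS):")
    print(spill.to_string(float_format="%.4f"))
    print(
        "\nThe precise editors concentrate edits on the stem-loop region "
        "(low spillover, high on/off ratio); the broad editor reaches into "
        "the CDS and edits more untethered transcripts."
    )
    print(f"\nTables written to {args.outdir}/reporter_*.tsv")


if __name__ == "__main__":
    main()
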