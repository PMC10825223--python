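"""Enzyme sequence-context bias: PCA recovery and CNN classification.

Study 1 simulates free A/U- and G/C-preferring editors in triplicate and
checks that their 16-dimensional flanking-context vectors separate on PC1
with loadings splitting A/U from G/C contexts.  Study 2 trains the
two-layer convolutional classifier to tell the two enzymes' cluster
windows apart (held-out AUC), with a permuted-label control.
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

    pca = studies.context_bias_recovery(seed=args.seed)
    clf = studies.classifier_study(seed=args.seed)
    out = {"context_pca": pca, "classifier": clf}
    print(json.dumps(out, indent=2))
    print(
        f"\nPC1 gap between enzymes is {pca['separation_ratio']:.1f}x the "
        f"replicate spread; the classifier reaches held-out AUC "
        f"{clf['auc_heldout']:.3f} versus {clf['auc_permuted']:.3f} on "
        "permuted labels."
    )
    Path(args.outdir).mkdir(parents=True, exist_ok=True)
    Path(args.outdir, "context_classifier.json").write_text(
        json.dumps(out, indent=2, sort_keys=True) + "\n"
    )


if __name__ == "__main__":
    main()
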