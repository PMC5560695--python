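"""Regenerate the bundled default 27-letter alphabet model.

Trains the Gaussian-emission HMM on the version-pinned synthetic
geometry corpus and writes src/saconf/data/default_model.json. Run from
the repository root:

    python scripts/train_default_model.py [--seed 2024]
"""

import argparse
import json
from pathlib import Path

from saconf.structural_alphabet import train_default_model


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2024)
    ap.add_argument("--out", default="src/saconf/data/default_model.json")
    args = ap.parse_args()
    model = train_default_model(seed=args.seed)
    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    # round to shrink the file; precision is far beyond fit uncertainty
    doc = json.loads(model.to_json())

    def roundf(x):
        if isinstance(x, float):
            return float(f"{x:.8g}")
        if isinstance(x, list):
            return [roundf(v) for v in x]
        return x

    for key in ("initial_probs", "transitions", "means", "covariances"):
        doc[key] = roundf(doc[key])
    # keep rows stochastic after rounding
    for row in doc["transitions"]:
        s = sum(row)
        row[:] = [v / s for v in row]
    s = sum(doc["initial_probs"])
    doc["initial_probs"] = [v / s for v in doc["initial_probs"]]
    out.write_text(json.dumps(doc))
    n_helix = sum(1 for v in model.ss_map.values() if v == "HELIX")
    n_strand = sum(1 for v in model.ss_map.values() if v == "STRAND")
    print(f"wrote {out} ({out.stat().st_size} bytes); "
          f"ss partition: {n_helix} helix / {n_strand} strand / "
          f"{27 - n_helix - n_strand} loop")


if __name__ == "__main__":
    main()
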