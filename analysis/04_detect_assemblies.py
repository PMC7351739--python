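"""Detect SPN-DAN assemblies in a synthetic multi-unit recording.

Builds a small population with known directed couplings, runs the
multi-scale detector with pruning, and summarizes the recovered pairs and
the directionality of their lags.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from mesolimbic import assemblies as asm, synthetic as syn


def main() -> None:
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--span", type=float, default=600.0, help="recording length (s)")
    p.add_argument("--out", type=Path, default=Path("results"))
    args = p.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(args.seed)
    trains, labels = [], {}
    # three coupled SPN->DAN pairs at 150 ms lag plus two independent units
    coup = syn.AssemblyCouplingSpec(lag_s=0.15, precision_s=0.03, efficacy=0.6)
    for k in range(3):
        a, b = syn.simulate_assembly_pair(
            syn.UnitSpec(role="SPN", baseline_hz=2.0),
            syn.UnitSpec(role="DAN", baseline_hz=4.0),
            coup, span_s=args.span, seed=int(rng.integers(2**31)),
            ids=(f"spn{k}", f"dan{k}"),
        )
        trains += [a, b]
        labels[a.unit_id], labels[b.unit_id] = "SPN", "DAN"
    for k in range(2):
        u = syn.simulate_unit(syn.UnitSpec(baseline_hz=3.0), span_s=args.span,
                              seed=int(rng.integers(2**31)), unit_id=f"ind{k}")
        trains.append(u)
        labels[u.unit_id] = "SPN"

    cfg = asm.ScaleConfig(deltas_s=(0.01, 0.03, 0.05, 0.08, 0.12, 0.25),
                          max_lag_bins=(20, 20, 20, 20, 10, 7))
    pairs = asm.detect_and_prune(trains, labels, cfg, seed=args.seed,
                                 n_surrogates=199)
    print(f"{len(pairs)} assemblies detected among "
          f"{len(trains) * (len(trains) - 1) // 2} unit pairs")
    rows = [{"unit_a": q.unit_a, "unit_b": q.unit_b, "label_a": q.label_a,
             "label_b": q.label_b, "delta_s": q.delta_s, "lag_bins": q.lag_bins,
             "lag_s": q.lag_s, "p_adjusted": q.p_adjusted} for q in pairs]
    df = pd.DataFrame(rows)
    print(df.to_string(index=False) if len(df) else "  (none)")
    direction = asm.lag_directionality(pairs)
    print(f"SPN->DAN lag distribution: n={direction['n']}, median "
          f"{direction.get('median_lag_s', float('nan')):.3f} s, sign test "
          f"p={direction['sign_test_p']:.4g}")

    df.to_csv(args.out / "assemblies.csv", index=False)
    with open(args.out / "assembly_directionality.json", "w") as fh:
        json.dump({k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in direction.items()}, fh, indent=2)
    print(f"wrote {args.out / 'assemblies.csv'}")


if __name__ == "__main__":
    main()
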