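#!/usr/bin/env python
"""Full-scale clustering benchmark (extended tier; hours of CPU, >8 GiB RAM).

Regenerates the full-size synthetic benchmarks (A: 500k barcodes at
rho=0.0033; B: 500k at 0.0066; C: 100k at 0.02; ~10-50M reads each), runs
the complete clustering pipeline, and reports FPC, FNC, the exact-count
fraction, and the effective-radius range.  This is deliberately NOT part of
the test suite -- run it on a machine with time to spare:

    python scripts/full_scale_benchmark.py --preset A --seed 1
    python scripts/full_scale_benchmark.py --preset C --seed 1 --scale 0.5
"""

from __future__ import annotations

import argparse
import json
import time

import shepherd as sh
from shepherd.evaluate import evaluate_clustering


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--preset", choices=["A", "B", "C"], required=True)
    parser.add_argument("--seed", type=int, required=True)
    parser.add_argument("--scale", type=float, default=1.0,
                        help="multiplier on the preset's barcode count")
    parser.add_argument("--out", default=None, help="optional JSON report path")
    args = parser.parse_args()

    cfg = sh.preset_config(args.preset, scale=args.scale, seed=args.seed)
    print(f"simulating {cfg.n_barcodes} barcodes at rho={cfg.rho} ...", flush=True)
    t0 = time.time()
    reads, truth = sh.generate_dataset(cfg)
    print(f"  {len(reads)} unique sequences, {reads.total_count} reads "
          f"({time.time() - t0:.0f}s)", flush=True)

    t0 = time.time()
    rho_hat = sh.estimate_rho(reads)
    epsilon = sh.choose_epsilon(reads, rho_hat)
    scheme = sh.make_scheme(reads.length, epsilon, n_sequences=len(reads))
    model = sh.ErrorModel(rho=rho_hat, l=reads.length, f_max=reads.f_max)
    print(f"  rho_hat={rho_hat:.6f} epsilon={epsilon} k={scheme.k} "
          f"({time.time() - t0:.0f}s)", flush=True)

    t0 = time.time()
    result = sh.cluster_reads(reads, scheme, model)
    print(f"  clustered into {len(result.clusters)} putative barcodes "
          f"({time.time() - t0:.0f}s)", flush=True)

    report = evaluate_clustering(result, truth)
    radii = report.r_e
    summary = {
        "preset": args.preset,
        "scale": args.scale,
        "seed": args.seed,
        "n_true_barcodes": report.n_true,
        "n_clusters": report.n_clusters,
        "fpc": report.fpc,
        "fnc": report.fnc,
        "exact_count_fraction": report.exact_count_fraction,
        "r_e_min": min(radii) if radii else None,
        "r_e_max": max(radii) if radii else None,
        "rho_hat": rho_hat,
        "epsilon": epsilon,
        "k": scheme.k,
    }
    print(json.dumps(summary, indent=2))
    if args.out:
        with open(args.out, "w") as fh:
            json.dump(summary, fh, indent=2)
            fh.write("\n")


if __name__ == "__main__":
    main()
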