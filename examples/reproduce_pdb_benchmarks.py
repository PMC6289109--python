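"""Rerun the outlier/MPR analysis on a deposited archive-metric table.

The deposited PDB metric datasets (one CSV per metric; see the README's
reproduction section for where to download them) are not bundled here.
Point this script at a downloaded table and it reruns the full pipeline:
natural-limit cleaning, density fitting, 5%/1% density-ranked outlier
boundaries, the 50% most probable range and the baseline comparison.

Example::

    python examples/reproduce_pdb_benchmarks.py \
        --input matthews.csv --column matthews --lower-limit 0
"""

import argparse

import pdrank as pk


def main() -> int:
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--input", required=True, help="deposited CSV table")
    p.add_argument("--column", required=True, help="metric column name")
    p.add_argument("--delimiter", default=",")
    p.add_argument("--lower-limit", type=float, default=None)
    p.add_argument("--upper-limit", type=float, default=None)
    p.add_argument("--fraction", type=float, default=0.5)
    args = p.parse_args()

    sample, report = pk.read_numeric_column(args.input, args.column, args.delimiter)
    if args.lower_limit is not None or args.upper_limit is not None:
        sample, clean = pk.apply_natural_limits(
            sample, args.lower_limit, args.upper_limit
        )
        print(f"natural-limit cleaning: kept {clean.retained}, "
              f"excluded {clean.excluded_below} below / {clean.excluded_above} above")

    model = pk.fit_density(sample)
    print(f"n = {sample.n}, bandwidth h = {model.bandwidth.h:.4f}")

    for level in (0.05, 0.01):
        res = pk.flag_pdr_outliers(sample, level, model)
        n_low = int((sample.values < res.lower_boundary).sum()) \
            if res.lower_boundary is not None else 0
        print(f"{level:.0%} PDR boundaries: lower {res.lower_boundary} "
              f"({n_low} entries below), upper {res.upper_boundary}")

    try:
        iv = pk.most_probable_range(sample, args.fraction, model)
    except pk.MultimodalError:
        iv = pk.most_probable_intervals(sample, args.fraction, model)
    pretty = ", ".join(f"[{lo:.3g}, {hi:.3g}]" for lo, hi in iv.intervals)
    print(f"{args.fraction:.0%} MPR: {pretty} (total length {iv.total_length:.3g})")

    print("\nbaseline comparison (5% level):")
    for r in pk.compare_methods(sample, 0.05, model):
        note = " [lower beyond natural limit]" if r.lower_meaningless else ""
        print(f"  {r.method:14s} lower={r.lower} upper={r.upper} "
              f"flagged={r.flagged_fraction:.2%}{note}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
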