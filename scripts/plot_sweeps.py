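"""Plot EER sweep tables produced by `asbit sweep` / metrics.run_sweep.

Emits the standard diagnostic figures: mean EER versus node count per event
rate, EER versus SNR, and EER versus code length.  Requires matplotlib
(`pip install asbit[plot]`).

Usage: python scripts/plot_sweeps.py sweep.csv --x n_nodes --by rate_hz --out eer.png
"""

from __future__ import annotations

import argparse

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("table", help="tidy sweep CSV")
    ap.add_argument("--x", default="n_nodes",
                    choices=["n_nodes", "rate_hz", "snr_db", "code_len"])
    ap.add_argument("--by", default=None, help="one curve per value of this column")
    ap.add_argument("--out", default="eer_sweep.png")
    args = ap.parse_args()

    df = pd.read_csv(args.table)
    df = df[df["eer"].notna()]
    keys = [args.x] + ([args.by] if args.by else [])
    g = df.groupby(keys, as_index=False).agg(mean_eer=("eer", "mean"),
                                             sem=("eer", "sem"))
    fig, ax = plt.subplots(figsize=(5, 3.5))
    if args.by:
        for val, sub in g.groupby(args.by):
            ax.errorbar(sub[args.x], sub["mean_eer"].clip(lower=1e-6),
                        yerr=sub["sem"], marker="o", capsize=2,
                        label=f"{args.by}={val:g}")
        ax.legend(frameon=False, fontsize=8)
    else:
        ax.errorbar(g[args.x], g["mean_eer"].clip(lower=1e-6), yerr=g["sem"],
                    marker="o", capsize=2)
    ax.axhline(1e-3, color="0.6", ls="--", lw=0.8)
    ax.set_xlabel(args.x)
    ax.set_ylabel("mean EER")
    ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(args.out, dpi=150)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
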