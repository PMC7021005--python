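"""Render summary figures from the tables written by 02 and 03.

Produces the deviation-vs-offset boxplot analog (per ROI, IMRT vs VMAT) and
the per-offset ROC curves at 3%/3mm.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ap = argparse.ArgumentParser()
ap.add_argument("--results", type=Path, default=Path("results"))
args = ap.parse_args()

fig_dir = args.results / "figures"
fig_dir.mkdir(parents=True, exist_ok=True)

sens = pd.read_csv(args.results / "sensitivity.csv")
at_w = sens[sens.width_mm == 4.5]

fig, axes = plt.subplots(2, 2, figsize=(10, 8), sharex=True)
for ax, roi in zip(axes.ravel(), ["PTV1_center", "PTV1_periphery", "PTV2", "SpinalCord"]):
    for tech, shift, color in (("imrt", -0.07, "C0"), ("vmat", 0.07, "C1")):
        sub = at_w[(at_w.roi == roi) & (at_w.technique == tech)]
        groups = [g.pct_dev.values for _, g in sub.groupby("offset_mm")]
        ax.boxplot(
            groups,
            positions=[p + shift for p in sorted(sub.offset_mm.unique())],
            widths=0.1,
            patch_artist=True,
            boxprops=dict(facecolor=color, alpha=0.6),
            medianprops=dict(color="black"),
        )
    ax.axhline(0.0, lw=0.5, color="gray")
    ax.set_title(roi)
    ax.set_xlabel("leaf-tip offset (mm)")
    ax.set_ylabel("% dose difference vs clinical model")
fig.suptitle("TLD dose deviation vs leaf-tip offset (width 4.5 mm; IMRT blue, VMAT orange)")
fig.tight_layout()
fig.savefig(fig_dir / "deviation_boxplots.png", dpi=120)
plt.close(fig)

curves = pd.read_csv(args.results / "roc_curves.csv")
fig, ax = plt.subplots(figsize=(6, 6))
sub33 = curves[curves.criteria == "3%/3mm"]
for dev, g in sub33[sub33.offset_deviation_mm > 0].groupby("offset_deviation_mm"):
    ax.plot(g.fpr, g.tpr, marker=".", label=f"offset deviation {dev:g} mm")
ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="chance")
ax.set_xlabel("false positive rate (1 - specificity)")
ax.set_ylabel("true positive rate (sensitivity)")
ax.set_title("QA detectability of leaf-tip offset errors (gamma 3%/3mm)")
ax.legend()
fig.tight_layout()
fig.savefig(fig_dir / "roc_curves.png", dpi=120)
plt.close(fig)

summary = pd.read_csv(args.results / "roc_summary.csv")
print(f"Figures written to {fig_dir}")
print("\nAUC summary:")
print(summary.to_string(index=False, float_format="%.3f"))
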