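"""Generate the synthetic nine-plan suite and write it to results/plans/.

Produces the plan manifest (composition, MU, seeds) and a per-plan aperture
table, plus the beam-model parameter file of the clinical model.
"""

import argparse
from pathlib import Path

import pandas as pd

from mlctip.io import save_beam_model, save_plan_csv
from mlctip.plans import generate_plan_suite
from mlctip.study import StudyConfig

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results/plans"))
args = ap.parse_args()

config = StudyConfig(master_seed=args.seed)
args.out.mkdir(parents=True, exist_ok=True)

suite = generate_plan_suite(config.master_seed)
manifest = pd.DataFrame(
    dict(
        plan_id=spec.plan_id,
        technique=spec.technique,
        n_beams_or_arcs=spec.n_beams_or_arcs,
        total_mu=spec.total_mu,
        modulation_strength=spec.modulation_strength,
        seed=spec.seed,
    )
    for spec, _ in suite
)
manifest.to_csv(args.out / "suite_manifest.csv", index=False)
for spec, plan in suite:
    save_plan_csv(plan, args.out / f"{spec.plan_id}.csv")
save_beam_model(config.clinical_model(), args.out / "clinical_model.yaml")

print(f"Wrote {len(suite)} plans to {args.out}")
print(manifest.to_string(index=False))
imrt = manifest[manifest.technique == "imrt"]
vmat = manifest[manifest.technique == "vmat"]
print(
    f"\nSuite: {len(imrt)} step-and-shoot plans ({sorted(imrt.n_beams_or_arcs)} beams) "
    f"and {len(vmat)} arc plans ({sorted(vmat.n_beams_or_arcs)} arcs); "
    f"total MU spans {manifest.total_mu.min():.0f}-{manifest.total_mu.max():.0f}."
)
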