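"""Which endpoints tell the exposure groups apart? Best-subset LDA searches.

Runs the leave-one-out cross-validated best-subset searches over the 12
biomarkers and over the 9 behavioural-class proportions, and prints the top
models of each pool.
"""

import pandas as pd

import ethomarker as em
from ethomarker import contingency as ct
from ethomarker import discriminant as da
from ethomarker import ethogram as eg
from ethomarker import synthetic as syn
from ethomarker.core import BIOMARKER_NAMES

study = em.simulate_study(
    syn.StudyDesign(), em.ArenaSpec(),
    syn.default_trajectory_params(seed=7, duration=20.0),
    syn.default_biomarker_params(seed=7),
)

bio = study.biomarkers
t_bio = da.FeatureTable(
    X=bio[list(BIOMARKER_NAMES)].reset_index(drop=True),
    groups=bio["condition"].reset_index(drop=True),
    provenance={c: "biomarker" for c in BIOMARKER_NAMES},
)
print(f"biomarker pool: {len(BIOMARKER_NAMES)} regressors, "
      f"{t_bio.n_obs} observations in {t_bio.n_groups} groups")
print("searching all 4095 subsets by LOOCV error ...")
res_bio = da.best_subsets_exhaustive(t_bio, tuple(BIOMARKER_NAMES))
print("top biomarker models:")
for r in res_bio[:3]:
    print(f"  {r.loocv_accuracy:5.1f}%  {'+'.join(r.subset)}")

frames = []
for traj in study.trajectories:
    d = em.assemble_descriptors(traj, window=1.0)
    frames.append(d[d["valid"]].assign(fish_id=traj.fish_id))
pooled = pd.concat(frames, ignore_index=True)
model = eg.train_som(pooled, eg.SOMConfig(seed=7, epochs=25))
labels = eg.assign_classes(model, pooled)
labels_by_fish = {
    f: g.to_numpy()
    for f, g in pd.Series(labels).groupby(pooled["fish_id"].to_numpy())
}
props = ct.build_profile(labels_by_fish, study.condition_map, "fish")
t_beh = da.FeatureTable(
    X=props.drop(columns="condition").reset_index(drop=True),
    groups=props["condition"].reset_index(drop=True),
    provenance={c: "behaviour" for c in props.columns if c != "condition"},
)
res_beh = da.best_subsets_exhaustive(t_beh, tuple(t_beh.X.columns))
print("\ntop behaviour models (class-frequency profiles):")
for r in res_beh[:3]:
    print(f"  {r.loocv_accuracy:5.1f}%  {'+'.join(r.subset)}")

print("\nBiomarkers separate the 8 exposure groups far better than behaviour")
print("frequencies alone; combining both pools is what the full pipeline")
print("(ethomarker run-all) does to look for 100%-accuracy models.")
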