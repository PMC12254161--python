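"""Does the behavioural-class profile depend on exposure concentration?

Builds the 8 x 9 condition-by-class contingency table of frame counts,
tests independence by chi-square with cell-wise Bonferroni-screened partial
chi-square values, and decomposes the association by correspondence analysis.
"""

import pandas as pd

import ethomarker as em
from ethomarker import contingency as ct
from ethomarker import ethogram as eg
from ethomarker import synthetic as syn

study = em.simulate_study(
    syn.StudyDesign(), em.ArenaSpec(),
    syn.default_trajectory_params(seed=7, duration=20.0),
    syn.default_biomarker_params(seed=7),
)
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
table = ct.build_profile(labels_by_fish, study.condition_map, "condition")
print(f"contingency table: {table.shape[0]} conditions x {table.shape[1]} classes\n")

chi = ct.chi_square_independence(table)
print(f"chi-square = {chi.statistic:.1f}, d.f. = {chi.df}, p = {chi.p:.3g}")
n_sig = int(chi.significant.to_numpy().sum())
print(f"{n_sig} of {chi.significant.size} cells exceed the Bonferroni-corrected")
print("partial chi-square threshold - class usage genuinely shifts with dose.\n")

ca = ct.correspondence_analysis(table)
print(f"total inertia = {ca.total_inertia:.4f} (= chi-square / n)")
for i, share in enumerate(ca.inertia_proportions[:3], start=1):
    print(f"  dimension {i}: {100 * share:.1f}% of the association")
print("\nThe first dimension orders conditions along the dose gradient:")
print(ca.row_coordinates.iloc[:, 0].round(3).to_string())
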