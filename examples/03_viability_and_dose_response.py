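"""Live/dead classification, well viability scores and Hill dose-response.

A 10-tree random forest per organoid line learns to separate DMSO controls
(live) from bortezomib / SN-38 positive controls (dead); averaging its binary
calls within a well gives a lethality score in [0, 1].  CTG luminescence
plates are edge-corrected and DMSO-normalised, and dilution series are
summarised by a Hill curve with an AUC in [0, 1].
"""

import numpy as np

import orgaprofiler as op
from orgaprofiler import synthetic_data as sd
from orgaprofiler.viability import evaluate_on_line

lib = sd.clinical_library_spec(n_drugs=4, seed=0)
plates = op.generate_plate_layout(["D004T", "D013T"], lib, seed=1)
cfg = op.EffectConfig(
    n_per_well=80,
    drug_effects={"clin_001": sd.DrugEffect(lethality=0.6)},
)
fm, truth = op.simulate_feature_table(plates, cfg, seed=5)

ldc = op.train_live_dead_classifier(fm, "D004T", seed=0)
print(f"live/dead classifier (D004T): validation accuracy "
      f"{ldc.validation_accuracy:.3f}, AUROC {ldc.validation_auroc:.3f}")
foreign = evaluate_on_line(ldc, fm, "D013T")
print(f"applied to the unseen line D013T: accuracy {foreign['accuracy']:.3f} "
      "(the death signature generalises across lines)")

scores = op.score_well_viability(ldc, fm)
drug = scores[scores["treatment"] == "clin_001"].sort_values("concentration")
print("well lethality scores for clin_001 (0 = all live, 1 = all dead):")
for row in drug.itertuples():
    print(f"  {row.concentration: .2e} M -> {row.score:.2f}")

# CTG normalisation + Hill fit on those lethality-derived viabilities
doses = drug["concentration"].to_numpy(dtype=float)
viability = 1.0 - drug["score"].to_numpy()
fit = op.fit_hill_auc(doses, viability)
print(f"Hill fit: EC50 = {fit.ec50 * 1e6:.2f} uM, slope = {fit.slope:.2f}, "
      f"E_inf = {fit.e_inf:.2f}, AUC = {fit.auc:.2f}")
print("AUC near 0 means no viability effect on the tested range; "
      "near 1 means a complete kill at every dose")

plate = plates[0]
lum = np.full((16, 24), 10_000.0) * (1 + 0.15 * np.arange(24) / 23)[None, :]
ctg = op.normalize_ctg_plate(lum, plate)
print(f"CTG plate with a 15% column gradient: after loess edge correction and "
      f"DMSO normalisation the well values are "
      f"{ctg['normalized'].min():.3f}..{ctg['normalized'].max():.3f} (ideal: 1.0)")
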