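"""PD-vs-HC classification with CPM and leave-one-out cross-validation.

Generates a cohort with a planted theta-band effect, profiles it, and runs
the full CPM LOOCV: per-fold univariate selection across a threshold grid,
z-scoring, per-band network strengths, logistic regression, and ROC/AUC on
the threshold-averaged P_PD scores.  Takes about half a minute.
"""

from tbpc.cpm import loocv, profiles_to_features, univariate_select
from tbpc.pipeline import RunConfig, compute_profiles
from tbpc.simulate import CohortSpec, gen_cohort

cohort = gen_cohort(CohortSpec(n_pd=20, n_hc=20, effect_size=2.0, seed=5),
                    n_channels=16, fs=250.0, duration=60.0)
profiles = compute_profiles(cohort.recordings, cohort.montage, RunConfig())
y = (cohort.subjects.set_index("subject_id")["group"] == "PD").astype(float)
fm = profiles_to_features(profiles, y)

report = loocv(fm, family="logistic", mode="group")
print(f"LOOCV AUC (threshold-averaged P_PD): {report.auc:.3f}")
for thr, auc in report.auc_per_threshold.items():
    print(f"  selection p < {thr:<7g} AUC = {auc:.3f}")

masks = univariate_select(fm.X, fm.y, 0.01, "group")
sel = masks.pos | masks.neg
frac = (fm.band_of[sel] == "theta").mean()
print(f"features selected at p<0.01: {sel.sum()}  "
      f"({100 * frac:.0f}% in theta, where the effect was planted)")
print()
print("P_PD is each subject's cross-validated probability of being a PD")
print("patient; AUC near 1 plus theta-dominated selection shows CPM both")
print("detects and localises the planted connectivity change.")
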