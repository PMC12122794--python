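"""Small end-to-end run: synthetic cohort -> features -> LOOCV -> metrics.

Uses a reduced model (hidden 16) and a strongly coupled cohort (delta = 5)
so the run finishes in about a minute; with only 8 subjects the held-out
AUC is still noisy (a fold's model sees just 7 subjects).
"""

from impact import (ModelConfig, SynthConfig, TrainConfig,
                    build_subject_features, compute_metrics, generate_cohort)
from impact.training import impact_factory, run_loocv

cohort = generate_cohort(SynthConfig(n_per_class=4, T=60, R=8, delta=5.0,
                                     event_windows=((10, 20), (35, 20)),
                                     affected_rois=(1, 2, 3), seed=1))
feats = [build_subject_features(s.roi, subject_id=s.subject_id, label=s.label,
                                n_ica=3, window_width=20, stride=10, seed=0)
         for s in cohort.subjects]

model_cfg = ModelConfig(hidden_dim=16, n_heads=2, n_layers=1, dropout=0.0,
                        ffn_expansion=2, classifier_width=8, roi_dim=8,
                        ica_dim=3, conn_dim=28, max_rel_offset=8)
train_cfg = TrainConfig(max_lr=1e-2, epochs=40, patience=10,
                        early_stopping=False, seed=0)

folds = run_loocv(impact_factory(model_cfg), feats, train_cfg)
report = compute_metrics(folds, n_resamples=1000, seed=0)
print("held-out predictions (subject, truth, p(patient)):")
for f in folds:
    print(f"  {f.subject_id}  {f.y_true}  {f.p1:.3f}")
print(f"LOOCV AUC {report.auc:.3f}  accuracy {report.accuracy:.3f}  "
      f"F1 {report.f1:.3f}  MCC {report.mcc:.3f}")
print(f"bootstrap 95% CI for AUC: {report.ci['auc']}")
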