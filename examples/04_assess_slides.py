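"""Full assessment pipeline: masks -> node instances -> scores -> counts.

Trains a quick classifier, calibrates the operating threshold by Matthews
correlation on a validation set, then counts positive/negative nodes on
multi-node slides and compares with the planted ground truth.
"""

import numpy as np

import slidestream as ss

mix = {"none": 0.5, "micro": 0.5}
train = ss.generate_study(40, lesion_mix=mix, canvas=256, seed=13)
net = ss.demo_net(np.random.default_rng(0))
ss.train_classifier(net, [(s.image, s.label) for s in train.slides],
                    epochs=3, seed=1, tile_size=128)

val = ss.generate_study(16, lesion_mix=mix, canvas=256, seed=113)
val_scores = [ss.score_image(net, s.image, tile_size=128) for s in val.slides]
table = ss.ScoreTable(np.arange(16), np.zeros(16), val_scores,
                      [s.label for s in val.slides])
threshold = ss.pick_threshold_mcc(table, np.round(np.linspace(0.05, 0.95, 19), 2))
print(f"operating threshold (max-MCC on validation): {threshold}")

study = ss.generate_study(3, nodes_per_slide=2, lesion_mix=mix, canvas=512, seed=501)
report = ss.run_study(study, net, threshold=threshold, tile_size=128)
for slide_report, slide in zip(report.slide_reports, study.slides):
    truth = sum(n.label for n in slide.nodes)
    print(f"{slide_report.slide_id}: predicted {slide_report.positive_count} positive / "
          f"{slide_report.negative_count} negative nodes (truth: {truth} positive), "
          f"scores {[round(s, 3) for s in slide_report.scores]}")
print(f"study rollup: {report.positive_count} positive, {report.negative_count} negative")
# Per-slide counts sum to the study rollup, mirroring the review panel that
# summarizes positive/negative node counts per slide and per study.
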