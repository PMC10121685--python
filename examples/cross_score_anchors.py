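"""Directional contact profiles (Cross-score): loop-anchor detection.

Simulates the kappa-like locus, computes per-bin upstream/downstream
long-range contact sums in the 30 kb - 1 Mb window, calls profile peaks, and
matches them to the ground-truth oriented barriers: peaks in the downstream
profile should sit at forward elements, upstream peaks at reverse elements.
Also detects the insulation gap separating the V cluster from the 3'
"regulatory loop" segment.
"""

from locifold import (CrossScoreParams, PipelineConfig, call_profile_peaks,
                      compute_cross_score, detect_score_gap, match_peaks_to_cbes,
                      simulate_locus, truth_to_annotation)
from locifold.pipeline import anchor_recovery

cfg = PipelineConfig()
matrix, truth, _ = simulate_locus("igk_like", wapl_level=2.2, config=cfg, seed=11)

profile = compute_cross_score(matrix, CrossScoreParams())  # 2 kb, 30 kb - 1 Mb
peaks = call_profile_peaks(profile, span=cfg.peak_span,
                           min_prominence=cfg.peak_min_prominence)
up = sum(p.side == "up" for p in peaks)
print(f"{len(peaks)} profile peaks ({up} upstream / {len(peaks) - up} downstream)")

report = anchor_recovery(peaks, truth, matrix.bins, tolerance_bins=2)
print(f"anchor recovery: precision {report['precision']:.2f}, "
      f"recall {report['recall']:.2f}, "
      f"orientation mismatches {report['n_orientation_mismatch']}")

gaps = detect_score_gap(profile, smooth_bins=25)
for g in gaps:
    print(f"insulation gap: bins {g.start_bin}-{g.end_bin} "
          f"({matrix.bins.starts[g.start_bin] / 1e6:.2f}-"
          f"{matrix.bins.starts[g.end_bin - 1] / 1e6:.2f} Mb)")

# Precision/recall ~1 means essentially every peak sits within +-2 bins of a
# barrier of the matching orientation; the gap near the 3' end marks the
# insulated regulatory-loop segment downstream of the Cer/Sis elements.
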