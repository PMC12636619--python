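"""Paired-pulse and train metrics from simulated iGluSnFR dF/F0 traces.

A facilitating paired-pulse protocol (two APs, 50 ms apart) yields the
paired-pulse ratio per ROI; a depressing 50-AP 20 Hz train yields the
cumulative release curve and the vesicle-replenishment rate (SVRR), the
slope of the cumulative signal over the last 30 APs.
"""

import numpy as np

from mfsyn import optophys, simulate

# paired-pulse facilitation
traces, truth = simulate.simulate_iglusnfr("facilitating", n_rois=50, seed=3)
pprs = []
for trace in traces:
    responses = optophys.detect_responses(trace)          # 4x SD, 10 ms window
    out = optophys.paired_pulse_ratio(responses)
    if out.ppr is not None:
        pprs.append(out.ppr)
print(f"facilitating preset: median PPR {np.median(pprs):.3f} over {len(pprs)} ROIs")
# PPR > 1 means the second response is larger: paired-pulse facilitation

# high-frequency train and replenishment
traces, _ = simulate.simulate_iglusnfr("depressing", n_rois=20, seed=4)
svrrs, finals = [], []
for trace in traces:
    responses = optophys.detect_responses(trace)
    cumulative = optophys.cumulative_release(responses)
    svrrs.append(optophys.svrr(cumulative, last_n=30))
    finals.append(cumulative[-1])
print(f"depressing preset: cumulative release {np.median(finals):.1f} dF/F0, "
      f"SVRR {np.median(svrrs):.3f} dF/F0 per AP")
# the SVRR is the steady-state release per AP late in the train, when
# release is limited by how fast vesicles are replenished
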