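"""Directed connectivity with TPDC, bootstrap threshold and time reversal.

Simulates three theta-resonant sources with a single directed coupling
1 -> 2, computes sliding-window partial directed coherence, a window-shuffle
bootstrap significance threshold, and the time-reversal check. Only the
planted connection should pass both stages.
"""

import numpy as np

from anxnet import effconn, simulate

fs = 125.0
model = simulate.oscillatory_mvar_model(fs, n_channels=3, peak_hz=5.5,
                                        couplings=[(1, 0, 0.35)])
signal = simulate.gen_mvar_signals(model, 30_000, seed=3)

params = dict(window_s=2.0, step_s=1.0, order=3,
              freqs=np.arange(1.0, 60.0), bands={"theta": (4.0, 7.0)})
null = effconn.bootstrap_threshold(signal, n_boot=200, shuffle_window_s=1.0,
                                   seed=3, **params)
decisions = effconn.time_reversal_test(signal, null, **params)

cols = ["target", "source", "forward", "threshold", "net_forward",
        "net_reversed", "passes"]
print(decisions[decisions["band"] == "theta"][cols].round(3).to_string(index=False))
# "forward" is the time-averaged theta-band PDC; a connection passes when it
# exceeds the bootstrap threshold AND its net direction flips sign on the
# time-reversed signal. Expect a single pass: ch1 <- ch0.
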