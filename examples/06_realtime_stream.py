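"""The 10-second real-time decision loop with a pluggable alert sink.

Replays a stream that turns ST-elevated halfway through; the loop emits
one decision per full 10 s buffer and a single debounced alert when the
episode begins.
"""

import numpy as np

from cardiosense import NoiseConfig, generate_record
from cardiosense.realtime import (record_stream, stream_decide,
                                  train_stream_models)

models = train_stream_models(seed=0)   # stands in for a shipped model

normal = generate_record("NORMAL", 21, noise=NoiseConfig(seed=4))
stemi = generate_record("ST_ELEVATION", 21, noise=NoiseConfig(seed=5))
samples = np.concatenate([normal.samples, stemi.samples])
stream = ((i / 500.0, v) for i, v in enumerate(samples))

alerts = []
for d in stream_decide(stream, 500.0, models, sinks=[alerts.append],
                       location=(25.29, 51.53)):
    print(f"t={d.end_time_s:5.1f} s  decision={d.label.value:<13} "
          f"ST dev {d.st_deviation_mv:+.3f} mV  ({d.n_beats} beats)")
print(f"{len(alerts)} alert emitted:", alerts[0].to_json())
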