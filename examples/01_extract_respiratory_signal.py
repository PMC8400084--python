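"""Render a thermopile scene and extract its respiratory signal.

A masked subject breathing at 20 bpm is rendered at 30 cm on an 8x8 grid,
then the Seg-AVG method (foreground K-means segmentation + spatial
averaging) turns the video into a one-dimensional respiratory trace.
"""

import numpy as np

import thermogate as tg

scene = tg.SceneConfig()  # mask ROI, 30 cm, 0.1 degC noise, 0.25 degC quantization
protocol = tg.ProtocolConfig(((60.0, 20.0),))
video, truth = tg.render_video(scene, protocol)
print(f"rendered {video.n_frames} frames of {video.shape} at {video.fps} fps")

signal = tg.extract_signal(video, "Seg-AVG", tg.WindowPlan(length_s=10.0))
print(f"extracted signal: {signal.values.size} samples, "
      f"peak-to-peak {np.ptp(signal.values):.3f} degC")

# correlation with the true breathing waveform shows the breathing rhythm
# survives sensor noise and quantization
rho = np.corrcoef(signal.values, truth.waveform.values)[0, 1]
print(f"correlation with ground-truth waveform: {rho:.3f}")
# expected: correlation well above 0.9 - the 20 bpm rhythm dominates the trace
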