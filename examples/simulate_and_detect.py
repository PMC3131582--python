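"""Render a short synthetic stream and run the recognizer over it.

Simulates half a second of 3 μm particles at 4 × 10⁶ /mL flowing through the
focused stream at 20 mm/s, imaged at 200 frames/s, then processes every frame
(background subtraction → |difference| threshold → blob features) and compares
detections with the generator's ground truth.
"""

from chipcyto import (
    ChipGeometry,
    FlowConfig,
    OpticsModel,
    ParticlePopulation,
    RecognitionConfig,
    make_background,
    process_frame,
    simulate_stream,
)

geometry, flow, optics = ChipGeometry(), FlowConfig(), OpticsModel()
pop = ParticlePopulation(label="3um", diameter_mean=3.0)
seq = simulate_stream([pop], [1.0], flow, geometry, optics,
                      density=4e6, duration=0.5, seed=42)
background = make_background(optics, seed=7)
recog = RecognitionConfig()

detections = []
for i, frame in enumerate(seq.frames):
    detections.extend(process_frame(frame, background, recog, optics, frame_index=i))

print(f"frames rendered:   {seq.n_frames}")
print(f"truth particles:   {len(seq.truth)} (one record per particle per frame)")
print(f"detections:        {len(detections)}")
d = detections[0]
print(f"first detection:   frame {d.frame_index}, centroid ({d.centroid[0]:.1f}, "
      f"{d.centroid[1]:.1f}) px, area {d.area_um2:.2f} um^2, "
      f"circularity {d.circularity:.2f}")
print("a 3 um disc projects ~7.1 um^2; detection count tracks truth because")
print("every fully visible particle clears the 25 ADU threshold at SNR 12.")
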