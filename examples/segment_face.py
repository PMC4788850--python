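"""Segment a synthetic face end to end and print its symmetry features.

A peripheral-palsy subject (asymmetry 0.5, right side affected) is
rendered for all five expressions, pushed through ROI detection,
window-kernel initialization, localized active contours, iris
segmentation and landmark extraction, and reduced to the ten symmetry
features f1..f10.
"""

from palsykit import pipeline as pl, synthetic as syn
from palsykit.features import FEATURE_NAMES

spec = syn.FaceSpec(palsy="peripheral", asymmetry=0.5, seed=11)
images, registries = {}, {}
for expression in syn.EXPRESSIONS:
    images[expression], registries[expression] = syn.render_face(spec, expression)

detector = syn.RegistryDetector(registries["rest"])
result = pl.run_subject(pl.SubjectRecord("demo", images), detector=detector)

print("subject: peripheral palsy, asymmetry 0.5, affected side right")
for name, value in zip(FEATURE_NAMES, result.features.values):
    print(f"  {name}: {value:.3f}")
print("forehead/eye features (f1-f6) depressed, as expected for the profile")
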