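"""Group contact midpoints into electrodes and number contacts
inner-to-outer (deepest contact = 1, the clinical convention)."""

import numpy as np

from seegviz import (
    PhantomSpec,
    assign_labels,
    brain_center,
    build_electrodes,
    make_ct_phantom,
    number_contacts,
)

spec = PhantomSpec(seed=1)
ct, brain, truth = make_ct_phantom(spec)
center = brain_center(brain)
print(f"brain centre: {np.round(center, 1)} mm")

# build from the planted contact positions (clean geometry)
electrodes = build_electrodes(truth.centers_mm(), center)
electrodes = [number_contacts(e, center) for e in electrodes]
anchors = {
    t.label: t.entry_mm.tolist() for t in spec.resolved_electrodes()
}
electrodes = assign_labels(electrodes, anchors)

for e in electrodes:
    depths = [f"{np.linalg.norm(p - center):.0f}" for p in e.points_mm]
    print(f"electrode {e.label}: {e.n_contacts} contacts "
          f"{e.contact_names()[0]}..{e.contact_names()[-1]}, "
          f"distance from centre (mm): {depths}")
# Chains grow from the outermost contact inward: successive contacts stay
# within 15 mm and bend less than 20 degrees, so parallel electrodes are
# never merged.
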