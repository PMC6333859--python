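"""Atlas-based VOI extraction and ipsi/contra pairing on a synthetic volume.

Paints known per-region curves into a labelled 4-D volume, extracts mean
TACs with the label atlas, and resolves ipsilateral/contralateral pairs
from the homolog table (hemispheres come from the lookup table, never from
voxel coordinates).
"""

import numpy as np

from epikinet import VOISelection, extract_voi_tacs, make_frame_schedule, pair_regions
from epikinet.synthetic_cohort import make_synthetic_atlas, paint_dynamic_volume

atlas = make_synthetic_atlas(n_pairs=6, shape=(20, 20, 10))
schedule = make_frame_schedule([(5, 60)])

rng = np.random.default_rng(0)
curves = {int(i): rng.uniform(5, 30, schedule.n_frames)
          for i in atlas.lut["label_id"]}
volume = paint_dynamic_volume(atlas, curves)

tacs = extract_voi_tacs(volume, atlas, [1, 7], schedule)
for key, tac in tacs.items():
    print(f"VOI {key} ({atlas.name(int(key))}): "
          f"extracted {np.round(tac.values, 2)}")
    print(f"          painted   {np.round(curves[int(key)], 2)}")

selection = VOISelection(epileptogenic=(1,), reference=(2, 3), focus_side="left")
for pair in pair_regions(atlas, selection):
    print(f"{pair['region_class']:18s} ipsi={pair['ipsi']} contra={pair['contra']}"
          f"  ({pair['name']})")
print("extraction is the voxel mean per frame; pairing maps each focus-side")
print("label to its mirror-hemisphere homolog.")
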