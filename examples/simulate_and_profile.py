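"""Simulate a positioning-element experiment and recover the signal.

Runs the "601-like" preset (a strong positioned site at each of two
element placements over 50% uniform background), pushes the fragments
through ingest, the 136-158 bp filter and dyad calling, and prints the
positioning score at each element center.  High scores at the element
centers against the ~0.07 uniform baseline are the recovered signal.
"""

import numpy as np

from nucprofile import (
    build_dyad_track,
    dyads_to_fragments,
    filter_by_length,
    positioning_at_element,
    positioning_scores,
    preset_experiment,
    simulate_dyads,
)

params = preset_experiment("positioning_601_like", n_fragments=50_000, seed=7)
dyads = simulate_dyads(params)
fragments, discarded = dyads_to_fragments(dyads, params)
retained, dropped = filter_by_length(fragments)
print(f"simulated {len(dyads)} dyads -> {len(fragments)} fragments "
      f"({discarded} off-reference), {len(retained)} in the 136-158 bp window")

track = build_dyad_track(retained, len(params.construct))
profile = positioning_scores(track)  # inner +/-10 bp over outer +/-150 bp

for report_pos, score in positioning_at_element(profile, params.construct, "601"):
    print(f"601 center at report position {report_pos:+d}: "
          f"positioning score {score:.3f}")
print(f"uniform-background baseline would be 21/301 = {21/301:.3f}; "
      "scores well above it mean nucleosomes are held in register at the element")
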