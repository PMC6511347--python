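"""Search the radar axis ordering that best separates blast populations.

Merges the gated blasts of one case from each group (the way a template
designer merges files of morphologically different AMLs), then compares the
published tube-3 layout with the ordering found by exhaustive search over
circular orderings.  The score is the minimum pairwise standardized centroid
distance between the three populations in the projection — higher means the
worst-separated pair of populations is further apart on the plot.
"""

import numpy as np

from radargate import (
    default_layouts,
    fit_scaling,
    gate_blasts,
    optimize_layout,
    project_radar,
    scale_to_unit,
    separation_score,
)
from radargate.events import EventMatrix
from radargate.synth import default_phenotypes, simulate_case

TUBE = 3
phenotypes = default_phenotypes()

blocks, labels = [], []
ref = None
for group, seed in [("hypergranular", 1), ("microgranular", 2), ("non_apl", 3)]:
    case = simulate_case(phenotypes[group], n_events=8000, seed=seed)
    em = case.tubes[TUBE]
    ref = ref if ref is not None else fit_scaling(em)
    blasts = gate_blasts(scale_to_unit(em, ref))
    blocks.append(blasts.events.values)
    labels += [group] * blasts.events.n_events
    first = em

merged = EventMatrix(values=np.vstack(blocks), channels=first.channels,
                     markers=dict(first.markers))
labels = np.array(labels)

published = default_layouts()[TUBE]
pub_score = separation_score(project_radar(merged, published), labels).aggregate
print(f"published tube-{TUBE} layout {published.channels}: score {pub_score:.3f}")

candidates = list(published.channels)  # same channels, order searched
best = optimize_layout(merged, labels, channels=candidates, tube_id=TUBE)
best_score = separation_score(project_radar(merged, best), labels).aggregate
print(f"optimized ordering        {best.channels}: score {best_score:.3f}")
print("\n(the optimizer can only reorder axes; a higher score means the two")
print(" APL types and the mimic separate more cleanly in this tube's plot)")
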