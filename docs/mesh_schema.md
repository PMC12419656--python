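# JSON mesh dialect

A tessellation is stored as a single JSON object with five required
top-level keys. All coordinates are micrometres in a y-up frame whose +x axis
is proximodistal (base → apex) and +y axis mediolateral (medial → lateral):
"top is lateral, right is apex".

```json
{
  "frame": {
    "pd_axis": [1.0, 0.0],
    "ml_axis": [0.0, 1.0],
    "pixel_size": 0.25
  },
  "cells": [
    {
      "cell_id": 1,
      "polygon": [[x, y], ...],
      "centroid": [x, y],
      "cell_type": "IHC",
      "domain": "sensory_medial",
      "kinocilium": [x, y],
      "channel_intensity": {"Cdh1": 0.93},
      "touches_boundary": false
    }
  ],
  "vertices": [
    {
      "vertex_id": 1,
      "position": [x, y],
      "incident_cells": [1, 2, 3],
      "interior": true
    }
  ],
  "bonds": [
    {
      "bond_id": 1,
      "endpoints": [1, 2],
      "flanking_cells": [1, 2],
      "polyline": [[x, y], ...],
      "intensity": {}
    }
  ],
  "provenance": "free text"
}
```

Field notes:

- `cell_id` are positive integers; `0` is reserved for the background/
  exterior and appears only in `flanking_cells`.
- `polygon` is an open ring (first point not repeated), simple, and
  counter-clockwise in the y-up frame.
- `cell_type` ∈ {IHC, OHC1, OHC2, OHC3, IPhC, pillar, Deiters, border, mKO,
  lKO, Hensen, Claudius, other}; `domain` ∈ {KO_medial, KO_lateral,
  sensory_medial, sensory_lateral, nonsensory_lateral} or null.
- `kinocilium` is null for cells without one.
- A vertex's `order` is `len(incident_cells)` plus one when `interior` is
  false (the background counts as one incident region on the tissue
  boundary).
- `polyline` runs from the first endpoint's position to the second's; bond
  length is its arc length.
- Missing required fields and dangling cross-references are rejected on load
  with an error naming the first offending field.

Annotation tables accompanying label images are plain CSV:
`cell_id,cell_type,domain` and, for kinocilia, `cell_id,x_um,y_um`.
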