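"""Independent brute-force oracle: frame-by-frame recount of sequences
and feature credits, sharing no code with the package's visit/event
pipeline."""

import numpy as np


def oracle_score_display(block, model_objects):
    """Return per-closed-sequence dicts with k and error flags.

    Scans raw frames directly: a sequence opens at a MODEL sample and
    closes at the next MODEL sample preceded by at least one RESOURCE
    sample; events are replayed with a per-object placement-history
    state machine and assigned to the sequence whose (open, close]
    index interval contains them.
    """
    aoi = block["aoi"].to_list()
    ev = block["controller_event"].to_list()
    held = block["held_object"].to_list()
    cell = block["placement_cell"].to_list()
    correct = block["placement_correct"].to_list()
    n = len(aoi)

    bounds = []
    open_i = None
    seen_r = False
    for i in range(n):
        if aoi[i] == "MODEL":
            if open_i is None:
                open_i = i
            elif seen_r:
                bounds.append((open_i, i))
                open_i = i
                seen_r = False
        elif aoi[i] == "RESOURCE" and open_i is not None:
            seen_r = True

    out = [{"k": 0, "identity": False, "location": False} for _ in bounds]
    misplaced = set()
    ever_wrong = set()
    prev_held = float("nan")
    for i in range(n):
        kind = ev[i]
        if kind in ("PICKUP", "RELEASE"):
            obj = held[i] if kind == "PICKUP" else prev_held
            seq = None
            for j, (a, b) in enumerate(bounds):
                if a < i <= b:
                    seq = j
                    break
            if not np.isnan(obj):
                obj = int(obj)
                if kind == "PICKUP":
                    if obj in misplaced:
                        misplaced.discard(obj)        # corrective re-pickup
                    elif obj not in model_objects:
                        if seq is not None:
                            out[seq]["identity"] = True
                    elif seq is not None:
                        out[seq]["k"] += 1
                elif not np.isnan(cell[i]):
                    if obj in ever_wrong:
                        pass                          # corrective placement
                    elif bool(correct[i]):
                        if seq is not None:
                            out[seq]["k"] += 1
                    else:
                        ever_wrong.add(obj)
                        misplaced.add(obj)
                        if seq is not None:
                            out[seq]["location"] = True
        prev_held = held[i]
    return out
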