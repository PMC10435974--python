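"""Independent literal-loop reference implementations used only by tests.

These deliberately avoid the package's own code paths: plain Python loops
over (trophic_group, cp_value, fresh_weight, predator) tuples, transcribing
each index and footprint definition directly.
"""

FREE_LIVING = ("Ba", "Fu", "Op")

ENRICHMENT_W = {("Ba", 1): 3.2, ("Fu", 2): 0.8}
BASAL_W = {("Ba", 2): 0.8, ("Fu", 2): 0.8}
STRUCTURE_W = {3: 1.8, 4: 3.2, 5: 5.0}


def oracle_indices(abund, rows):
    """MI, PPI, WI, NCR, EI, SI (None where undefined) by direct transcription."""
    items = [(g, a, *rows[g]) for g, a in abund.items() if a > 0]

    def cp_mean(predicate):
        tot = wsum = 0.0
        for _, a, group, cp, _, _ in items:
            if predicate(group):
                tot += a
                wsum += cp * a
        return wsum / tot if tot > 0 else None

    MI = cp_mean(lambda g: g in FREE_LIVING)
    PPI = cp_mean(lambda g: g == "Pp")

    ba = sum(a for _, a, g, *_ in items if g == "Ba")
    fu = sum(a for _, a, g, *_ in items if g == "Fu")
    pp = sum(a for _, a, g, *_ in items if g == "Pp")
    WI = (ba + fu) / pp if pp > 0 else None
    NCR = ba / (ba + fu) if ba + fu > 0 else None

    e = b = s = 0.0
    for _, a, group, cp, _, predator in items:
        if (group, cp) in ENRICHMENT_W:
            e += ENRICHMENT_W[(group, cp)] * a
        if (group, cp) in BASAL_W:
            b += BASAL_W[(group, cp)] * a
        if group in FREE_LIVING and cp >= 3:
            s += STRUCTURE_W[cp] * a
        elif cp == 2 and predator:
            s += 0.8 * a
    EI = 100.0 * e / (e + b) if e + b > 0 else None
    SI = 100.0 * s / (s + b) if s + b > 0 else None
    return {"MI": MI, "PPI": PPI, "WI": WI, "NCR": NCR, "EI": EI, "SI": SI}


def oracle_footprints(abund, rows):
    """Per-group and per-life-history footprint sums by direct transcription."""
    groups = {"Ba": 0.0, "Fu": 0.0, "Pp": 0.0, "Op": 0.0}
    fe = fs = total = 0.0
    for g, a in abund.items():
        if a <= 0:
            continue
        group, cp, w, _ = rows[g]
        f = a * (0.1 * w / cp + 0.273 * w**0.75)
        groups[group] += f
        total += f
        if cp <= 2:
            fe += f
        else:
            fs += f
    return {**groups, "total": total, "Fe": fe, "Fs": fs}
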