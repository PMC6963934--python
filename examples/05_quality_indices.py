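"""Compute juice quality indices and compare the two sweetness rankings.

TSS/TA divides sugars by acids; BrimA (TSS - 10*TA) subtracts them, which
weights acidity the way the tongue does. The two indices need not order
samples the same way — that disagreement is exactly what a sensory panel
can arbitrate.
"""

import senslex as sl

samples = [
    # TSS %, TA g malic acid/100 g; weights (dish, +fresh, +dry) g; CIELAB L*, a*, b*
    sl.JuiceSample("Pinova", 14.63, 0.583, weights=(30.0, 45.0, 32.1), lab=(44.2, -1.5, 20.1)),
    sl.JuiceSample("Gravensteiner", 11.02, 0.672, weights=(30.0, 45.0, 31.6), lab=(45.0, 1.2, 16.3)),
    sl.JuiceSample("Rouge", 12.72, 0.902, weights=(30.0, 45.0, 31.9), lab=(38.5, 6.8, 17.9)),
    sl.JuiceSample("Jonagold", 13.42, 0.512, weights=(30.0, 45.0, 32.0), lab=(39.9, 6.1, 26.4)),
    sl.JuiceSample("Elstar", 12.96, 0.576, weights=(30.0, 45.0, 31.9), lab=(42.8, 0.4, 21.7)),
    sl.JuiceSample("Rubinette", 15.63, 0.983, weights=(30.0, 45.0, 32.3), lab=(43.6, -0.9, 19.5)),
]

table = sl.index_table(samples, k=10.0, threshold=20.0)
cols = ["ratio_tss_ta", "rank_by_ratio", "brima", "rank_by_brima",
        "sweet_sour_class", "dm_pct", "chroma", "hue_deg"]
print(table[cols].round(2).to_string())

ratio_top = table["rank_by_ratio"].idxmin()
brima_top = table["rank_by_brima"].idxmin()
print(f"\nsweetest by TSS/TA ratio: {ratio_top}; sweetest by BrimA: {brima_top}")
print("The indices disagree on the top sample (and on the sour tail), because "
      "BrimA penalizes acidity additively instead of by division; hue near 90 "
      "degrees reads as yellow, lower values shift toward red.")
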