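"""Inspect the bundled sensory wheel and build a small custom one.

The selectable set — outer-ring descriptors plus the four generic
odor/aroma subcategories — is the attribute universe the citation chance
model counts: its size d drives every probability downstream.
"""

import senslex as sl

wheel = sl.load_default_wheel()
print(f"wheel '{wheel.name}': {len(wheel.outer_ring())} outer-ring descriptors, "
      f"{wheel.n_selectable} selectable attributes (d)")
for macro, subs in wheel.categories:
    parts = [f"{s.name}{'*' if s.selectable else ''}({len(s.descriptors)})" for s in subs]
    print(f"  {macro}: {', '.join(parts)}")
print("  (* = the subcategory itself may be cited)")

lexicon = sl.RankedLexicon((("sweet", 165), ("sour", 141), ("bitter", 53)))
config = {
    "name": "mini",
    "categories": [{
        "macro_category": "taste",
        "subcategories": [
            {"name": "taste", "selectable": False,
             "descriptors": ["sweet", "sour", "bitter", "umami"]},
        ],
    }],
}
mini, unresolved = sl.build_wheel(lexicon, config, additions={"umami"})
print(f"\ncustom wheel: d = {mini.n_selectable}, unresolved descriptors: {unresolved}")
print("Every config descriptor must come from the mined lexicon or be an "
      "explicit addition; duplicates and empty categories are rejected.")
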