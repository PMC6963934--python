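# Default apple-juice sensory wheel shipped with senslex.
#
# SYNTHETIC FIXTURE: the published wheel figure is not machine-readable, so
# this file assembles every descriptor the accompanying study names in its
# text and normalization table, padded with generic apple-lexicon terms to
# exactly 42 outer-ring descriptors. The four odor/aroma subcategories
# (vegetable, fruity, toasted, spicy) are themselves selectable, giving a
# selectable attribute set of 46 — the size the citation-probability model
# assumes by default.
name: apple-juice-default
categories:
  - macro_category: taste
    subcategories:
      - name: taste
        selectable: false
        descriptors: [sweet, sour, bitter, intensity, persistence, strong-taste, balanced, complex]
  - macro_category: mouthfeel
    subcategories:
      - name: mouthfeel
        selectable: false
        descriptors: [astringent, metallic, pungent]
  - macro_category: appearance & texture
    subcategories:
      - name: appearance
        selectable: false
        descriptors: [cloudy, clarified, bodied, light, dark, yellowish, reddish]
  - macro_category: odor & aroma notes
    subcategories:
      - name: vegetable
        selectable: true
        descriptors: [green-apple, grassy, herbaceous, hay, earthy]
      - name: fruity
        selectable: true
        descriptors: [ripe-apple, pear, lemon, citrus, tropical, berry, floral, honey]
      - name: toasted
        selectable: true
        descriptors: [caramel, candy, cooked, nutty, smoky, burnt]
      - name: spicy
        selectable: true
        descriptors: [cinnamon, clove, medicinal, musty, artificial]
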