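# PROMIS Scale v1.2 - Global Health: item and subscale definitions.
#
# Items are stored in the raw direction of administration.  Reverse-direction
# items (Global08 fatigue, Global10 emotional problems) carry an explicit
# recode map so that after recoding a higher scored category always means
# better health.  Global07 (pain, 0-10 numerical rating) is banded onto the
# 1-5 scored scale; the banding is configuration, not code, so that other
# conventions can be swapped in.
instrument: PROMIS-GH
version: "1.2"
item_order:
  [Global01, Global02, Global03, Global04, Global05,
   Global06, Global07, Global08, Global09, Global10]
items:
  Global01:
    content: general health
    raw_scale: [1, 2, 3, 4, 5]
    reverse_coded: false
  Global02:
    content: quality of life
    raw_scale: [1, 2, 3, 4, 5]
    reverse_coded: false
  Global03:
    content: physical health
    raw_scale: [1, 2, 3, 4, 5]
    reverse_coded: false
  Global04:
    content: mental health
    raw_scale: [1, 2, 3, 4, 5]
    reverse_coded: false
  Global05:
    content: satisfaction with social activities and relationships
    raw_scale: [1, 2, 3, 4, 5]
    reverse_coded: false
  Global06:
    content: everyday physical activities
    raw_scale: [1, 2, 3, 4, 5]
    reverse_coded: false
  Global07:
    content: pain average (0 = no pain, 10 = worst pain imaginable)
    raw_scale: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
    reverse_coded: true
    recode_map:
      0: 5
      1: 4
      2: 4
      3: 4
      4: 3
      5: 3
      6: 3
      7: 2
      8: 2
      9: 2
      10: 1
  Global08:
    content: fatigue average (1 = none, 5 = very severe)
    raw_scale: [1, 2, 3, 4, 5]
    reverse_coded: true
  Global09:
    content: usual activities and roles
    raw_scale: [1, 2, 3, 4, 5]
    reverse_coded: false
  Global10:
    content: emotional problems frequency (1 = never, 5 = always)
    raw_scale: [1, 2, 3, 4, 5]
    reverse_coded: true
subscales:
  GMH: [Global02, Global04, Global05, Global10]
  GMH-2a: [Global04, Global05]
  GPH: [Global03, Global06, Global07, Global08]
  GPH-2a: [Global03, Global06]
anchor_item: Global01
standalone_items: [Global01, Global09]
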