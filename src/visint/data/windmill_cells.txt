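# Windmill contour cell map (synthetic layout, frozen for reproducibility).
# Four straight 10-cell arms in an open pinwheel arrangement around
# fixation, plus two filler cells extending the two vertical arms so the
# element count (42) matches the square contour.
# Columns: row col orientation_deg   (0 = vertical, 90 = horizontal)
# arm 1: vertical, left of and above center (extended by one filler cell)
1 13 0
2 13 0
3 13 0
4 13 0
5 13 0
6 13 0
7 13 0
8 13 0
9 13 0
10 13 0
11 13 0
# arm 2: vertical, right of and below center (extended by one filler cell)
12 19 0
13 19 0
14 19 0
15 19 0
16 19 0
17 19 0
18 19 0
19 19 0
20 19 0
21 19 0
22 19 0
# arm 3: horizontal, above and right of center
8 17 90
8 18 90
8 19 90
8 20 90
8 21 90
8 22 90
8 23 90
8 24 90
8 25 90
8 26 90
# arm 4: horizontal, below and left of center
15 6 90
15 7 90
15 8 90
15 9 90
15 10 90
15 11 90
15 12 90
15 13 90
15 14 90
15 15 90
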