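"""Closed-form spatial statistics on a 2x2 checkerboard.

A perfect +1/-1 checkerboard is the textbook extreme of negative spatial
autocorrelation: every neighbor pair has opposite sign.  With sample-sd
z-scores and row-normalized rook weights, Moran's I hits its lower limit
-1, each local Moran is -1/4, Geary's C is 4(n-1)/(2n) = 1.5, and each
local Geary is 3.
"""

import lisakit as lk

dataset = lk.checkerboard_dataset(2, 2)
W = lk.row_normalize(lk.contiguity_weights(dataset.areas, "rook"))
z = lk.znormalize(dataset.values[:, 0])

print("global Moran's I :", lk.global_moran(W, z))
print("local Moran's I  :", lk.local_moran(W, z))
print("global Geary's C :", lk.global_geary(W, z))
print("local Geary's C  :", lk.local_geary(W, z))
print("spatial lag      :", lk.spatial_lag(W, z), "(each cell's neighbor mean = -z_i)")
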