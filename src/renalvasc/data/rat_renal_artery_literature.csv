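# Literature mean vessel radii (um) per Strahler order for the rat renal
# arterial tree, from vascular-cast micro-CT morphometry (Nordsletten et al.
# 2006, Am J Physiol Renal Physiol 291:F296-F309, Table 2; orders 0-2 and the
# root order 10). These are measured reference values, not package output.
order,radius_mean
0,10.08
1,13.90
2,20.06
10,216.10
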