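# Editable per-gene boundary catalogue: gene -> ordered [id, facing]
# pairs along the antero-posterior axis.  'anterior' means the boundary
# delimits the anterior edge of its expression domain (intensity rises
# towards the posterior); 'posterior' the converse.  gt IDs 3-4 are
# reserved to keep numbering consistent with homologous boundaries in
# other species.  Facings other than the documented gt set are package
# defaults and may be edited to match a given stain panel.
bcd:
- [1, posterior]
cad:
- [1, anterior]
hb:
- [1, posterior]
- [2, anterior]
- [3, posterior]
Kr:
- [1, anterior]
- [2, posterior]
kni:
- [1, anterior]
- [2, posterior]
gt:
- [2, posterior]
- [5, anterior]
- [6, posterior]
- [7, anterior]
tll:
- [1, posterior]
- [2, anterior]
hkb:
- [1, posterior]
- [2, anterior]
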