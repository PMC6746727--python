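# Material registry: one section per material, pointing at a packaged
# mass-attenuation table (TSV) and carrying the bulk density in g/cm^3.
# Edge energies (keV) list the absorption edges duplicated in the table.

[hydrogen]
table = hydrogen.tsv
density = 8.375e-5

[carbon]
table = carbon.tsv
density = 1.70

[nitrogen]
table = nitrogen.tsv
density = 1.165e-3

[oxygen]
table = oxygen.tsv
density = 1.332e-3

[calcium]
table = calcium.tsv
density = 1.55

[iodine]
table = iodine.tsv
density = 4.93
edges = 33.1694

[gadolinium]
table = gadolinium.tsv
density = 7.90
edges = 50.2396

[water]
table = water.tsv
density = 1.00

[soft_tissue]
table = water.tsv
density = 1.06

[air]
table = air.tsv
density = 1.205e-3

[pvp]
table = pvp.tsv
density = 1.20

[whewellite]
table = whewellite.tsv
density = 2.23

[weddellite]
table = weddellite.tsv
density = 1.94
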