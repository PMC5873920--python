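name	chrom	category	pseudogene
GNE	chr9	biosynthesis	0
NANS	chr9	biosynthesis	0
NANP	chr20	biosynthesis	0
RENBP	chrX	biosynthesis	0
CMAH	chr6	modification	1
CMAS	chr12	activation_transport_transfer	0
SLC35A1	chr6	activation_transport_transfer	0
ST3GAL1	chr8	activation_transport_transfer	0
ST3GAL2	chr16	activation_transport_transfer	0
ST3GAL3	chr1	activation_transport_transfer	0
ST3GAL4	chr11	activation_transport_transfer	0
ST3GAL5	chr2	activation_transport_transfer	0
ST3GAL6	chr3	activation_transport_transfer	0
ST6GAL1	chr3	activation_transport_transfer	0
ST6GAL2	chr2	activation_transport_transfer	0
ST6GALNAC1	chr17	activation_transport_transfer	0
ST6GALNAC2	chr17	activation_transport_transfer	0
ST6GALNAC3	chr1	activation_transport_transfer	0
ST6GALNAC4	chr9	activation_transport_transfer	0
ST6GALNAC5	chr1	activation_transport_transfer	0
ST6GALNAC6	chr9	activation_transport_transfer	0
ST8SIA1	chr12	activation_transport_transfer	0
ST8SIA2	chr15	activation_transport_transfer	0
ST8SIA3	chr18	activation_transport_transfer	0
ST8SIA4	chr5	activation_transport_transfer	0
ST8SIA5	chr18	activation_transport_transfer	0
ST8SIA6	chr10	activation_transport_transfer	0
SIGLEC1	chr20	recognition	0
CD22	chr19	recognition	0
CD33	chr19	recognition	0
MAG	chr19	recognition	0
SIGLEC5	chr19	recognition	0
SIGLEC6	chr19	recognition	0
SIGLEC7	chr19	recognition	0
SIGLEC8	chr19	recognition	0
SIGLEC9	chr19	recognition	0
SIGLEC10	chr19	recognition	0
SIGLEC11	chr19	recognition	0
SIGLEC12	chr19	recognition	0
SIGLEC14	chr19	recognition	0
SIGLEC15	chr18	recognition	0
SIGLEC16	chr19	recognition	0
SELP	chr1	recognition	0
SELE	chr1	recognition	0
SELL	chr1	recognition	0
LAMA2	chr6	recognition	0
L1CAM	chrX	recognition	0
NEU1	chr6	recycling_degradation	0
NEU2	chr2	recycling_degradation	0
NEU3	chr11	recycling_degradation	0
NEU4	chr2	recycling_degradation	0
SIAE	chr11	recycling_degradation	0
NPL	chr1	recycling_degradation	0
CTSA	chr20	recycling_degradation	0
SLC17A5	chr6	recycling_degradation	0
HEXA	chr15	recycling_degradation	0
HEXB	chr5	recycling_degradation	0
GLB1	chr3	recycling_degradation	0
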