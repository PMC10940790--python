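"""Reported NW Atlantic herring divergence loci.

Coordinates of the divergence regions and structural variants between
spring and fall spawning herring (Atlantic herring reference assembly,
1-based inclusive).  These serve as worked examples for the interval
arithmetic and as region definitions for structural-variant analyses.
"""

from .intervals import GenomicInterval

#: Putative structural variant distinguishing spring and fall spawners,
#: ~7.7 Mb at one end of chromosome 8.
SV_CHR8 = GenomicInterval("Chr8", 23_040_136, 30_729_461)

#: Known ~7.8 Mb inversion on chromosome 12 underlying the north-south
#: latitudinal pattern among fall spawners.
INVERSION_CHR12 = GenomicInterval("Chr12", 17_826_318, 25_603_093)

#: Five distinct spawning-time loci within the 4-Mb selection signal on
#: chromosome 15, in genomic order (rab15-sipa1l1, sox11b, tshr-calm1b,
#: flrt2-lncRNA, esr2a-syne2-l3hypdh).
CHR15_LOCI = (
    GenomicInterval("Chr15", 6_750_000, 7_000_000),
    GenomicInterval("Chr15", 7_650_000, 7_850_000),
    GenomicInterval("Chr15", 8_540_000, 9_070_000),
    GenomicInterval("Chr15", 9_200_000, 9_350_000),
    GenomicInterval("Chr15", 10_820_000, 11_100_000),
)

#: Two loci on chromosome 19 (herpud2-adgrb1b and the sweep-like
#: lncRNA/sgk-like locus).
CHR19_LOCI = (
    GenomicInterval("Chr19", 20_290_000, 20_700_000),
    GenomicInterval("Chr19", 23_155_000, 23_300_000),
)

#: All printed divergence loci keyed by a short label.
NAMED_LOCI = {
    "sv_chr8": SV_CHR8,
    "inversion_chr12": INVERSION_CHR12,
    "chr15_rab15_sipa1l1": CHR15_LOCI[0],
    "chr15_sox11b": CHR15_LOCI[1],
    "chr15_tshr_calm1b": CHR15_LOCI[2],
    "chr15_flrt2_lncrna": CHR15_LOCI[3],
    "chr15_esr2a_syne2": CHR15_LOCI[4],
    "chr19_herpud2_adgrb1b": CHR19_LOCI[0],
    "chr19_lncrna_sgk": CHR19_LOCI[1],
}
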