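"""Reference per-gene counts from a published 50-case CSVD exome burden screen.

A published whole-exome screen of 50 CADASIL-referred cerebral small-vessel
disease cases tested cell-cell adhesion genes for an excess of rare,
predicted-deleterious variants against the gnomAD v2.1.1 exome controls
(125,748 individuals). Its dominant-model table prints, per gene, the case
heterozygous-carrier count, case total allele count, control total allele
count, and the one-sided Fisher p with BH FDR; the recessive-model table
prints compound-heterozygote and homozygote carrier counts. These printed
counts are inputs here: rebuilding the dominant 2x2 from them — case
carriers = HET + HOM individuals, control carriers = total allele count
(each allele in a distinct individual) — must reproduce the printed
p-values, which validates the test construction end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

CONTROL_N = 125_748
N_CASES = 50


@dataclass(frozen=True)
class DominantReferenceRow:
    gene: str
    case_het: int
    case_hom: int  # from the recessive-model table (hom carriers also count as dominant)
    control_total_ac: int
    p_dom: float
    fdr_dom: float

    @property
    def dominant_carriers(self) -> int:
        return self.case_het + self.case_hom


#: The five top dominant-model genes with full printed counts. Only ARVCF has
#: a homozygous carrier; the others' recessive-table HOM columns are zero.
DOMINANT_TOP5: tuple[DominantReferenceRow, ...] = (
    DominantReferenceRow("TENM3", 22, 0, 10_397, 1.38e-11, 3.63e-09),
    DominantReferenceRow("CNTN4", 18, 0, 7_943, 6.56e-10, 8.63e-08),
    DominantReferenceRow("ARVCF", 16, 1, 7_463, 2.11e-09, 1.85e-07),
    DominantReferenceRow("LRRC7", 15, 0, 5_896, 5.54e-09, 3.22e-07),
    DominantReferenceRow("SCRIB", 23, 0, 15_738, 6.12e-09, 3.22e-07),
)

#: All 49 dominant-model (p, FDR) pairs, in printed order, for the implied
#: BH family-size diagnostic (the screen's effective m is not printed).
DOMINANT_P_FDR: tuple[tuple[str, float, float], ...] = (
    ("TENM3", 1.38e-11, 3.63e-09),
    ("CNTN4", 6.56e-10, 8.63e-08),
    ("ARVCF", 2.11e-09, 1.85e-07),
    ("LRRC7", 5.54e-09, 3.22e-07),
    ("SCRIB", 6.12e-09, 3.22e-07),
    ("DSCAM", 1.01e-08, 4.43e-07),
    ("IGFN1", 2.55e-08, 9.58e-07),
    ("TENM2", 3.05e-08, 1.00e-06),
    ("PKP4", 7.19e-08, 2.10e-06),
    ("IGSF9", 1.35e-07, 3.56e-06),
    ("SDK2", 1.50e-07, 3.60e-06),
    ("BSG", 3.97e-07, 8.70e-06),
    ("CDH12", 7.75e-07, 1.57e-05),
    ("CDHR2", 1.91e-06, 3.58e-05),
    ("ROBO4", 2.89e-06, 5.07e-05),
    ("TENM4", 4.61e-06, 7.58e-05),
    ("DSP", 6.43e-06, 9.95e-05),
    ("DSCAML1", 6.92e-06, 1.01133e-04),
    ("FAT3", 1.27e-05, 1.75345e-04),
    ("CDHR3", 1.49e-05, 1.96526e-04),
    ("DLG2", 1.84e-05, 2.30134e-04),
    ("FAT1", 2.22e-05, 2.65077e-04),
    ("LGALS9C", 2.52e-05, 2.88451e-04),
    ("IL27RA", 3.96e-05, 4.31162e-04),
    ("CNTN2", 4.10e-05, 4.31162e-04),
    ("DLG4", 4.95e-05, 5.00568e-04),
    ("CELSR2", 7.06e-05, 6.88141e-04),
    ("MYPN", 8.14e-05, 7.64551e-04),
    ("DSG4", 1.07471e-04, 9.74654e-04),
    ("FBLIM1", 1.37799e-04, 1.208036e-03),
    ("SDK1", 1.46387e-04, 1.241927e-03),
    ("DLG1", 1.61883e-04, 1.330475e-03),
    ("DSC2", 4.05688e-04, 3.154362e-03),
    ("CNTN6", 4.07788e-04, 3.154362e-03),
    ("FAT2", 5.67347e-04, 4.263207e-03),
    ("CDH22", 7.02417e-04, 5.131546e-03),
    ("LRFN3", 7.4463e-04, 5.286837e-03),
    ("FAM49B", 7.6504e-04, 5.286837e-03),
    ("OBSL1", 7.8398e-04, 5.286837e-03),
    ("DSG1", 9.98318e-04, 6.563942e-03),
    ("IGSF21", 5.041989e-03, 3.2342515e-02),
    ("PODXL", 5.693263e-03, 3.565067e-02),
    ("CDH10", 6.313734e-03, 3.8616556e-02),
    ("DSC3", 7.026878e-03, 4.2001567e-02),
    ("LIMS2", 7.409349e-03, 4.2362149e-02),
    ("PODXL2", 7.369466e-03, 4.2362149e-02),
    ("CDH6", 7.705581e-03, 4.3118467e-02),
    ("CDH9", 8.363126e-03, 4.5151173e-02),
    ("PTPRS", 8.412196e-03, 4.5151173e-02),
)

#: Recessive-model reference row used to exercise both control-side
#: strategies (its printed p is NOT reproducible from these counts under
#: either strategy — the screen's recessive control construction is not
#: fully determined by summary statistics — so only the counts are used).
ARVCF_RECESSIVE = {
    "case_ch": 6,
    "case_hom": 1,
    "control_nhom": 0,
    "control_total_ac": 7_463,
}
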