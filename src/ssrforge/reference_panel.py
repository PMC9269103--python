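"""Published characterization of the 17-marker Dalmatian pyrethrum panel.

Per-locus statistics of the 17 genomic SSR markers developed for
*Tanacetum cinerariifolium*, scored on 20 individuals from one natural
population: allele count (Na), observed/expected heterozygosity (Ho, He),
inbreeding coefficient (Fis), Hardy-Weinberg significance flag after
sequential Bonferroni correction, null-allele frequency where detected
(Pnull), polymorphic information content (PIC) and probability of
identity (PI).  Serves as a fixed input for panel-level aggregation and
for cross-checking the closed-form statistics implemented here.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = ["load_reference_panel", "DIVERSITY_SUBSET", "MINING_COUNTS"]

_PANEL_TSV = """\
locus	Na	Ho	He	Fis	hwe_significant	Pnull	PIC	PI
TcUniZg004	4	0.167	0.235	0.29	False	NA	0.219	0.605
TcUniZg005	4	0.304	0.449	0.322	False	NA	0.384	0.37
TcUniZg006	13	0.542	0.633	0.145	False	NA	0.605	0.158
TcUniZg007	5	0.333	0.505	0.339	False	0.091	0.432	0.318
TcUniZg008	11	0.708	0.864	0.18	False	NA	0.824	0.043
TcUniZg009	6	0.583	0.774	0.246	False	0.111	0.716	0.098
TcUniZg010	6	0.667	0.757	0.12	False	NA	0.697	0.11
TcUniZg012	5	0.391	0.542	0.277	False	NA	0.485	0.266
TcUniZg013	4	0.375	0.323	-0.16	False	NA	0.288	0.495
TcUniZg014	6	0.542	0.531	-0.021	False	NA	0.488	0.263
TcUniZg017	7	0.542	0.704	0.23	False	NA	0.639	0.146
TcUniZg019	5	0.583	0.72	0.19	False	NA	0.654	0.137
TcUniZg020	3	0.083	0.197	0.576	False	0.111	0.178	0.668
TcUniZg023	3	0.458	0.433	-0.059	False	NA	0.35	0.405
TcUniZg032	3	0.5	0.592	0.155	False	NA	0.506	0.25
TcUniZg037	4	0.125	0.299	0.582	True	0.146	0.266	0.528
TcUniZg038	5	0.542	0.702	0.228	False	NA	0.634	0.15
"""

#: The 12 markers retained for the three-population diversity study
#: (null-allele loci and the lowest-information locus excluded).
DIVERSITY_SUBSET = [
    "TcUniZg005", "TcUniZg006", "TcUniZg008", "TcUniZg010", "TcUniZg012",
    "TcUniZg013", "TcUniZg014", "TcUniZg017", "TcUniZg019", "TcUniZg023",
    "TcUniZg032", "TcUniZg038",
]

#: Genome-wide mining yield for the same species (contig counts from the
#: two assembly routes combined): SSR-containing contigs and how many of
#: those carry more than one locus.
MINING_COUNTS = {
    "total_contigs": 6_909_675,
    "total_ssr_loci": 35_556,
    "ssr_containing_contigs": 31_380,
    "contigs_with_multiple_ssrs": 3_272,
    "primer_pairs_tested": 56,
    "markers_developed": 17,
}


def load_reference_panel() -> pd.DataFrame:
    """The per-locus characterization table as a DataFrame."""
    return pd.read_csv(StringIO(_PANEL_TSV), sep="\t", na_values="NA")
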