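"""Built-in reference study design: 60 population sample sets and a 46-variant
vitamin D panel.

The roster reproduces the published multi-population design this package
targets: 18 European (EUR, 972 subjects), 24 East Asian (EAS, 795) and 18
Sub-Saharan African (AFR, 866) cohorts drawn from ALFRED and 1000 Genomes,
with their cohort sizes and latitude points or ranges. Longitudes are not part
of the published roster; the values here are synthetic, hand-assigned once
from each cohort's country/region so that raster-cell lookup has a location to
work with (the bundled synthetic UVB raster varies with latitude only, so the
choice does not affect any statistic).

The variant panel carries the ALFRED fixation indices, minor-allele
frequencies, variant alleles and dbSNP function classes of the 46 retained
vitamin D-pathway variants, and the published per-group mean variant-allele
frequencies for the three pigmentation ancestry-validation markers and the 16
vitamin D production/transport variants (DHCR7/NADSYN1 and GC loci), together
with their published distribution-pattern labels. These group means serve as
generative truth for the synthetic cohort generator.
"""

from __future__ import annotations

import io

import pandas as pd

from .data_io import SampleSet, VariantAnnotation, read_sample_sets, read_variant_annotations

# The Mongolian (China) cohort has no published latitude: coordinates are NA
# and the set is excluded from UVB aggregation only.
_SAMPLE_SETS_TSV = """\
id\tname\tgroup\tn\tlat_min\tlat_max\tlon\tsource
DANES\tDanes\tEUR\t51\t55.0\t58.0\t10.0\tALFRED
FINNS\tFinns\tEUR\t36\t60.0\t75.0\t26.0\tALFRED
ORCAD\tOrcadian\tEUR\t16\t59.0\t59.0\t-3.0\tALFRED
IRISH\tIrish\tEUR\t116\t51.0\t56.0\t-8.0\tALFRED
FRENCH\tFrench\tEUR\t28\t46.0\t46.0\t2.0\tALFRED
BASQUE\tBasque (France)\tEUR\t24\t43.0\t43.0\t-1.0\tALFRED
HUNG\tHungarians\tEUR\t92\t45.5\t48.5\t19.0\tALFRED
TUSCAN\tItalian (Tuscan)\tEUR\t8\t43.0\t43.0\t11.0\tALFRED
BERGAMO\tItalian (Bergamo)\tEUR\t14\t46.0\t46.0\t9.7\tALFRED
SARD\tSardinian\tEUR\t28\t40.0\t40.0\t9.0\tALFRED
VOLOGDA\tRussians (Vologda)\tEUR\t25\t61.0\t61.0\t40.0\tALFRED
ARCHAN\tRussians (Archangel'sk)\tEUR\t34\t63.0\t64.5\t40.5\tALFRED
CHUVASH\tChuvash\tEUR\t42\t54.5\t56.5\t47.0\tALFRED
ADYGEI\tAdygei (Krasnodar)\tEUR\t54\t44.0\t45.0\t40.0\tALFRED
GBR\tBritish from England and Scotland (GBR)\tEUR\t91\t49.8\t59.5\t-2.0\tKG1000
FIN\tFinnish in Finland (FIN)\tEUR\t99\t60.0\t75.0\t26.0\tKG1000
IBS\tIberians in Spain (IBS)\tEUR\t107\t36.0\t43.5\t-4.0\tKG1000
TSI\tToscani in Italia (TSI)\tEUR\t107\t38.0\t47.0\t11.0\tKG1000
AMI\tAmi (Taiwan)\tEAS\t40\t22.5\t24.0\t121.0\tALFRED
ATAYAL\tAtayal (Taiwan)\tEAS\t41\t21.8\t25.5\t121.3\tALFRED
DAI\tDai (China)\tEAS\t10\t21.0\t21.0\t100.0\tALFRED
DAUR\tDaur (China)\tEAS\t10\t48.0\t49.0\t124.0\tALFRED
HAN\tHan (China)\tEAS\t45\t36.0\t39.0\t114.0\tALFRED
HEZHEN\tHezhen (China)\tEAS\t10\t47.0\t48.0\t133.0\tALFRED
JPN\tJapanese\tEAS\t29\t38.0\t38.0\t138.0\tALFRED
KOREAN\tKoreans\tEAS\t53\t34.5\t43.0\t127.5\tALFRED
LAHU\tLahu (China)\tEAS\t10\t22.0\t22.0\t100.0\tALFRED
MIAO\tMiao (China)\tEAS\t10\t28.0\t28.0\t109.0\tALFRED
NAXI\tNaxi (China)\tEAS\t10\t26.0\t26.0\t100.2\tALFRED
OROQEN\tOroqen (China)\tEAS\t10\t48.0\t53.0\t122.0\tALFRED
SHE\tShe (China)\tEAS\t10\t27.0\t27.0\t119.0\tALFRED
TU\tTu (China)\tEAS\t10\t36.0\t36.0\t101.9\tALFRED
TUJIA\tTujia (China)\tEAS\t10\t29.0\t29.0\t109.0\tALFRED
UYGUR\tUygur (China)\tEAS\t10\t44.0\t44.0\t81.0\tALFRED
XIBO\tXibo (China)\tEAS\t9\t43.0\t44.0\t81.5\tALFRED
YIZU\tYizu (China)\tEAS\t10\t28.0\t28.0\t103.0\tALFRED
HAKKA\tHakka (Taiwan)\tEAS\t43\t22.0\t35.0\t116.0\tALFRED
MONGOL\tMongolian (China)\tEAS\t10\tNA\tNA\tNA\tALFRED
CDX\tChinese Dai in Xishuangbanna, China (CDX)\tEAS\t93\t21.0\t28.0\t100.8\tKG1000
CHB\tHan Chinese in Beijing, China (CHB)\tEAS\t103\t22.0\t40.0\t116.4\tKG1000
CHS\tHan Chinese South, China (CHS)\tEAS\t105\t22.0\t40.0\t113.0\tKG1000
JPT\tJapanese in Tokyo, Japan (JPT)\tEAS\t104\t30.0\t46.0\t139.7\tKG1000
BANTU_SA\tBantu (South Africa)\tAFR\t8\t-29.0\t-22.0\t25.0\tALFRED
BANTU_KE\tBantu (Kenya)\tAFR\t12\t-3.0\t-3.0\t37.0\tALFRED
SAN\tSan (Namibia)\tAFR\t7\t-21.0\t-21.0\t20.0\tALFRED
BIAKA\tBiaka (C. African Republic)\tAFR\t35\t4.0\t4.0\t17.0\tALFRED
HAUSA\tHausa (Nigeria)\tAFR\t39\t7.0\t18.0\t8.0\tALFRED
IBO\tIbo (Nigeria)\tAFR\t48\t5.0\t7.0\t7.0\tALFRED
MBUTI\tMbuti (DR Congo)\tAFR\t19\t1.0\t1.0\t29.0\tALFRED
YORUBA\tYoruba (Nigeria)\tAFR\t25\t6.0\t10.0\t4.0\tALFRED
CHAGGA\tChagga (Tanzania)\tAFR\t45\t-3.5\t-2.5\t37.3\tALFRED
MASAI\tMasai (E Africa)\tAFR\t22\t-6.0\t1.0\t36.0\tALFRED
SANDAWE\tSandawe (Tanzania)\tAFR\t39\t-7.0\t-4.0\t35.0\tALFRED
ZARAMO\tZaramo (Tanzania)\tAFR\t39\t-11.0\t-4.0\t38.8\tALFRED
MANDENKA\tMandenka (Senegal)\tAFR\t24\t12.0\t12.0\t-12.0\tALFRED
ESN\tEsan in Nigeria (ESN)\tAFR\t99\t4.0\t12.0\t6.0\tKG1000
GWD\tGambian in Western Division, Mandinka (GWD)\tAFR\t113\t7.0\t23.0\t-15.0\tKG1000
YRI\tYoruba in Ibadan, Nigeria (YRI)\tAFR\t108\t6.0\t10.0\t4.0\tKG1000
LWK\tLuhya in Webuye, Kenya (LWK)\tAFR\t99\t-3.0\t1.0\t34.8\tKG1000
MSL\tMende in Sierra Leone (MSL)\tAFR\t85\t4.0\t10.0\t-11.8\tKG1000
"""

# 46 retained vitamin D-pathway variants with ALFRED fixation indices.
_VARIANT_PANEL_TSV = """\
rsid\tlocus\tvariant_allele\tmaf\tfst\tfunction_class
rs11632698\tCYP11A1\tG\t0.35\t0.18\tIntron
rs2073475\tCYP11A1\tA\t0.38\t0.13\tnearGene-5
rs3787557\tCYP24A1\tC\t0.12\t0.13\tIntron
rs927650\tCYP24A1\tT\t0.34\t0.14\tIntron
rs912505\tCYP24A1\tG\t0.39\t0.14\tIntron
rs2762929\tCYP24A1\tT\t0.39\t0.15\tIntron
rs4809956\tCYP24A1\tC\t0.40\t0.18\tIntron
rs7568196\tCYP27A1\tA\t0.25\t0.14\tIntron
rs4674338\tCYP27A1\tG\t0.25\t0.17\tIntron
rs13013510\tCYP27A1\tG\t0.43\t0.18\tIntron
rs691414\tCYP27A1\tC\t0.06\t0.30\tIntron
rs692290\tCYP27A1\tG\t0.11\t0.38\tIntron
rs16930625\tCYP2R1\tG\t0.15\t0.14\t5' UTR
rs11023374\tCYP2R1\tC\t0.17\t0.17\tIntron
rs3750997\tDHCR7/NADSYN1\tT\t0.42\t0.16\tIntron
rs1790325\tDHCR7/NADSYN1\tA\t0.26\t0.18\tIntron
rs11603330\tDHCR7/NADSYN1\tA\t0.35\t0.18\tIntron
rs7928249\tDHCR7/NADSYN1\tA\t0.42\t0.20\tnearGene-5
rs12800438\tDHCR7/NADSYN1\tG\t0.40\t0.16\tIntron
rs7944926\tDHCR7/NADSYN1\tA\t0.35\t0.22\tIntron
rs3794060\tDHCR7/NADSYN1\tT\t0.35\t0.23\tIntron
rs12280295\tDHCR7/NADSYN1\tC\t0.05\t0.53\tIntron
rs7041\tGC\tG\t0.38\t0.14\tMissense
rs4364228\tGC\tG\t0.17\t0.14\tIntron
rs222047\tGC\tG\t0.38\t0.16\tIntron
rs3737549\tGC\tT\t0.10\t0.16\tIntron
rs222016\tGC\tA\t0.34\t0.17\tIntron
rs222020\tGC\tT\t0.34\t0.17\tIntron
rs843006\tGC\tG\t0.36\t0.19\tIntron
rs705117\tGC\tA\t0.42\t0.25\tIntron
rs1805343\tRXRA\tA\t0.48\t0.16\tIntron
rs1805352\tRXRA\tA\t0.47\t0.16\tIntron
rs10881582\tRXRA\tG\t0.38\t0.18\tIntron
rs3118571\tRXRA\tA\t0.48\t0.19\tIntron
rs3818740\tRXRA\tT\t0.38\t0.20\tIntron
rs731516\tRXRA\tA\t0.11\t0.43\tIntron
rs7040434\tRXRA\tC\t0.15\t0.51\tIntron
rs283695\tRXRG\tA\t0.34\t0.14\tIntron
rs12069160\tRXRG\tT\t0.14\t0.15\tIntron
rs10800098\tRXRG\tA\t0.12\t0.16\tIntron
rs10489745\tRXRG\tC\t0.17\t0.17\tIntron
rs886441\tVDR\tC\t0.23\t0.13\tIntron
rs2283342\tVDR\tC\t0.19\t0.13\tIntron
rs2107301\tVDR\tT\t0.34\t0.16\tIntron
rs4334089\tVDR\tG\t0.41\t0.17\tIntron
rs4516035\tVDR\tC\t0.18\t0.18\t2KB upstream
"""

# Published cohort-weighted group mean variant-allele frequencies for the
# vitamin D production (DHCR7/NADSYN1) and transport (GC) variants, with the
# published distribution-pattern labels, and for the three pigmentation
# ancestry-validation markers.
_GROUP_MEANS_TSV = """\
rsid\tlocus\tEUR\tEAS\tAFR\tpattern
rs3750997\tDHCR7/NADSYN1\t0.30\t0.58\t0.65\tEUR_DIFFERS
rs1790325\tDHCR7/NADSYN1\t0.95\t0.73\t0.57\tEUR_DIFFERS
rs11603330\tDHCR7/NADSYN1\t0.69\t0.35\t0.11\tALL_DIFFER
rs7928249\tDHCR7/NADSYN1\t0.29\t0.66\t0.63\tEUR_DIFFERS
rs12800438\tDHCR7/NADSYN1\t0.30\t0.63\t0.66\tEUR_DIFFERS
rs7944926\tDHCR7/NADSYN1\t0.30\t0.63\t0.86\tALL_DIFFER
rs3794060\tDHCR7/NADSYN1\t0.70\t0.37\t0.11\tALL_DIFFER
rs12280295\tDHCR7/NADSYN1\t0.00\t0.00\t0.23\tAFR_DIFFERS
rs7041\tGC\t0.58\t0.28\t0.10\tALL_DIFFER
rs4364228\tGC\t0.09\t0.12\t0.45\tAFR_DIFFERS
rs222047\tGC\t0.58\t0.23\t0.12\tALL_DIFFER
rs3737549\tGC\t0.00\t0.14\t0.22\tEUR_DIFFERS
rs222016\tGC\t0.85\t0.62\t0.37\tALL_DIFFER
rs222020\tGC\t0.85\t0.62\t0.36\tALL_DIFFER
rs843006\tGC\t0.83\t0.62\t0.31\tALL_DIFFER
rs705117\tGC\t0.84\t0.50\t0.17\tALL_DIFFER
"""

_PIGMENTATION_MEANS_TSV = """\
rsid\tlocus\tEUR\tEAS\tAFR
rs1426654\tSLC24A5\t0.99\t0.03\t0.08
rs16891982\tSLC45A2\t0.91\t0.01\t0.00
rs1800414\tOCA2\t0.00\t0.59\t0.00
"""


def reference_sample_sets() -> list[SampleSet]:
    """The 60-cohort reference roster (18 EUR + 24 EAS + 18 AFR)."""
    return read_sample_sets(io.StringIO(_SAMPLE_SETS_TSV))


def reference_variant_panel() -> list[VariantAnnotation]:
    """The 46-variant vitamin D panel with ALFRED fixation indices."""
    return read_variant_annotations(io.StringIO(_VARIANT_PANEL_TSV))


def reference_group_means() -> pd.DataFrame:
    """Published per-group means for DHCR7/NADSYN1 and GC variants.

    Columns: rsid, locus, EUR, EAS, AFR, pattern (published distribution-
    pattern label). Index: rsid.
    """
    return pd.read_csv(io.StringIO(_GROUP_MEANS_TSV), sep="\t", index_col="rsid")


def pigmentation_group_means() -> pd.DataFrame:
    """Published per-group means for the ancestry-validation pigmentation markers."""
    return pd.read_csv(io.StringIO(_PIGMENTATION_MEANS_TSV), sep="\t", index_col="rsid")


def group_subject_totals() -> dict[str, int]:
    """Summed cohort sizes per geographic group for the reference roster."""
    totals: dict[str, int] = {}
    for s in reference_sample_sets():
        totals[s.group] = totals.get(s.group, 0) + s.n
    return totals
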