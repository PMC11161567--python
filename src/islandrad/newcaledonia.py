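"""Encoded species-tree topology for the New Caledonian arecoid palm
radiation and its four focal clades.

The topology transcribes the published species-tree description of the
radiation: four well-supported New Caledonian clades (the expanded genus
Chambeyronia; the Burretiokentia + Cyphophoenix grade; Basselinia; and
Clinospermatinae, i.e. Cyphokentia + Clinosperma) embedded in the wider
western Pacific clade of tribe Areceae, with Cyphosperma balansae a fifth,
single-tip New Caledonian lineage. Genus- and subtribe-level relationships
and most species-level sister pairs are fixed by the published description;
a handful of species placements left unresolved there (five Basselinia
species and the attachment of the Chambeyronia lepidota + C. piersoniorum
pair) are filled with one documented resolution consistent with the
published speciation-event survey. One Basselinia tip carries a placeholder
label (``Basselinia_sp``). Branch lengths are not part of the encoding: the
event survey is purely topological.
"""

from __future__ import annotations

from .trees import Phylogeny, read_tree

__all__ = [
    "NEW_CALEDONIA_NEWICK",
    "FOCAL_CLADES",
    "new_caledonia_tree",
    "focal_clades",
]

_CHAMBEYRONIA = (
    "((((Chambeyronia_divaricata,Chambeyronia_huerlimanii),"
    "Chambeyronia_pyriformis),"
    "((Chambeyronia_macrocarpa,Chambeyronia_oliviformis),"
    "Chambeyronia_magnifica)),"
    "(Chambeyronia_lepidota,Chambeyronia_piersoniorum))"
)

_BURRETIOKENTIA_CYPHOPHOENIX = (
    "(Cyphophoenix_fulcita,(Cyphophoenix_alba,"
    "((Cyphophoenix_elegans,Cyphophoenix_nucele),"
    "((Burretiokentia_vieillardii,Burretiokentia_hapala),"
    "((Burretiokentia_dumasii,Burretiokentia_koghiensis),"
    "Burretiokentia_grandiflora)))))"
)

_BASSELINIA = (
    "(((Basselinia_moorei,Basselinia_velutina),"
    "((Basselinia_humboldtiana,Basselinia_deplanchei),Basselinia_glabrata)),"
    "(((Basselinia_pancheri,(Basselinia_vestita,"
    "(Basselinia_gracilis,Basselinia_eriostachys))),Basselinia_sp),"
    "(((Basselinia_tomentosa,Basselinia_favieri),Basselinia_sordida),"
    "Basselinia_iterata)))"
)

_CLINOSPERMATINAE = (
    "((Cyphokentia_macrostachya,Cyphokentia_cerifera),"
    "((Clinosperma_vaginata,Clinosperma_bracteale),Clinosperma_macrocarpa))"
)

# Basseliniinae + Rhopalostylidinae block: the Burretiokentia/Cyphophoenix
# grade is sister to Physokentia; Cyphosperma + Lepidorrhachis group with
# Basselinia; Rhopalostylidinae branch outside those three.
_BASSELINIINAE = (
    "((Physokentia_petiolata," + _BURRETIOKENTIA_CYPHOPHOENIX + "),"
    "(Rhopalostylis_sapida,((Cyphosperma_balansae,Lepidorrhachis_mooreana),"
    + _BASSELINIA + ")))"
)

NEW_CALEDONIA_NEWICK = (
    "(Euterpe_edulis,(Hydriastele_wendlandiana,"
    "((((" + _CLINOSPERMATINAE + ",Carpoxylon_macrospermum),"
    "(Heterospathe_elata,Dransfieldia_micrantha)),"
    "(Laccospadix_australasicus,(Linospadix_monostachyos,Howea_forsteriana))),"
    "((" + _BASSELINIINAE + "),"
    "((Ptychosperma_macarthurii,(Archontophoenix_cunninghamiana,"
    + _CHAMBEYRONIA + ")),Calyptrocalyx_hollrungii)))));"
)

FOCAL_CLADES: dict[str, tuple[str, ...]] = {
    "Chambeyronia": (
        "Chambeyronia_divaricata", "Chambeyronia_huerlimanii",
        "Chambeyronia_pyriformis", "Chambeyronia_macrocarpa",
        "Chambeyronia_oliviformis", "Chambeyronia_magnifica",
        "Chambeyronia_lepidota", "Chambeyronia_piersoniorum",
    ),
    "Burretiokentia_Cyphophoenix": (
        "Cyphophoenix_fulcita", "Cyphophoenix_alba", "Cyphophoenix_elegans",
        "Cyphophoenix_nucele", "Burretiokentia_vieillardii",
        "Burretiokentia_hapala", "Burretiokentia_dumasii",
        "Burretiokentia_koghiensis", "Burretiokentia_grandiflora",
    ),
    "Basselinia": (
        "Basselinia_moorei", "Basselinia_velutina", "Basselinia_humboldtiana",
        "Basselinia_deplanchei", "Basselinia_glabrata", "Basselinia_pancheri",
        "Basselinia_vestita", "Basselinia_gracilis", "Basselinia_eriostachys",
        "Basselinia_sp", "Basselinia_tomentosa", "Basselinia_favieri",
        "Basselinia_sordida", "Basselinia_iterata",
    ),
    "Clinospermatinae": (
        "Cyphokentia_macrostachya", "Cyphokentia_cerifera",
        "Clinosperma_vaginata", "Clinosperma_bracteale",
        "Clinosperma_macrocarpa",
    ),
}


def new_caledonia_tree() -> Phylogeny:
    """The encoded species tree (37 New Caledonian tips plus relatives)."""
    return read_tree(NEW_CALEDONIA_NEWICK)


def focal_clades() -> list[tuple[str, ...]]:
    """The four multi-species New Caledonian focal clades, as tip sets."""
    return list(FOCAL_CLADES.values())
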