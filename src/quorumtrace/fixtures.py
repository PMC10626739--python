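"""Bundled fixture reference database and worked-example catalog.

The fixture DB mirrors the structure of the oral-biofilm QS reference set:
ten signal classes with both synthase-side and receptor entries (the
"complete" pathways) and eleven further signal classes represented by a
single role only (the "incomplete" pathways), 21 signals in total. Protein
names and signal classes follow the field's nomenclature (AgrD/AgrC,
Pfs/LuxS/LsrB, RpfF/RpfR, ...); the amino-acid sequences are synthetic —
deterministic draws from natural residue frequencies — because the artifact
never touches the network. Sequence content does not matter for any
consumer: homology search only ever compares catalog genes against these
same references.
"""

from __future__ import annotations

import numpy as np

from .reference import ReferenceDB, ReferenceQSProtein, Role

#: approximate natural amino-acid frequencies (Swiss-Prot composition)
AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
AA_FREQS = np.array(
    [
        0.0826, 0.0137, 0.0546, 0.0672, 0.0386, 0.0708, 0.0227, 0.0593,
        0.0580, 0.0965, 0.0241, 0.0406, 0.0474, 0.0393, 0.0553, 0.0660,
        0.0535, 0.0687, 0.0110, 0.0292,
    ]
)
AA_FREQS = AA_FREQS / AA_FREQS.sum()

_FIXTURE_SEED = 20231106

# (protein name, signal, role, step, source organism, domain keyword)
# The ten complete pathways: both a synthase-side and a receptor entry.
_COMPLETE = [
    ("AgrD", "AIP_Agr-Fsr_Like", "synthase", None, "Streptococcus pneumoniae R6", "agrD propeptide"),
    ("AgrC", "AIP_Agr-Fsr_Like", "receptor", None, "Streptococcus pneumoniae R6", "agrC histidine kinase"),
    ("NisA", "Lantibiotics", "synthase", 1, "Lactococcus lactis subsp. lactis", "lantibiotic precursor"),
    ("NisC", "Lantibiotics", "processor", None, "Lactococcus lactis subsp. lactis", "lantibiotic cyclase"),
    ("NisK", "Lantibiotics", "receptor", None, "Lactococcus lactis subsp. lactis", "nisK sensor kinase"),
    ("CbnS", "Bacteriocin-II", "synthase", None, "Carnobacterium maltaromaticum", "class II bacteriocin"),
    ("CbnK", "Bacteriocin-II", "receptor", None, "Carnobacterium maltaromaticum", "cbnK sensor kinase"),
    ("Pfs", "AI-2", "synthase", 1, "Salmonella enterica", "MTA/SAH nucleosidase"),
    ("LuxS", "AI-2", "synthase", 2, "Bacteroides vulgatus", "S-ribosylhomocysteine lyase"),
    ("AibA", "AI-2", "receptor", None, "Helicobacter pylori", "AI-2 receptor AibA"),
    ("LsrB", "AI-2", "receptor", None, "Escherichia coli", "autoinducer-2 binding protein LsrB"),
    ("LuxP", "AI-2", "receptor", None, "Vibrio harveyi", "periplasmic AI-2 binding LuxP"),
    ("PhrC", "AIP_RRNPP", "synthase", None, "Bacillus subtilis", "phr peptide precursor"),
    ("Rgg", "AIP_RRNPP", "receptor", None, "Streptococcus pyogenes", "RRNPP transcriptional regulator"),
    ("RpfB", "DSF", "synthase", 1, "Xanthomonas campestris", "fatty acyl-CoA ligase RpfB"),
    ("RpfF", "DSF", "synthase", 2, "Xanthomonas campestris", "enoyl-CoA hydratase RpfF"),
    ("RpfR", "DSF", "receptor", None, "Burkholderia cenocepacia", "PAS-GGDEF DSF receptor"),
    ("RpfC", "DSF", "receptor", None, "Xanthomonas campestris", "rpfC hybrid sensor kinase"),
    ("PqsD", "HAQ", "synthase", None, "Pseudomonas aeruginosa PAO1", "anthraniloyl-CoA synthetase"),
    ("PqsR", "HAQ", "receptor", None, "Pseudomonas aeruginosa PAO1", "LysR-type receptor PqsR"),
    ("LuxI", "AHL", "synthase", None, "Vibrio fischeri", "acyl-homoserine-lactone synthase"),
    ("AinR", "AHL", "receptor", None, "Vibrio fischeri", "AHL sensor kinase AinR"),
    ("CqsA", "AHK", "synthase", None, "Vibrio cholerae", "CAI-1 autoinducer synthase"),
    ("CqsS", "AHK", "receptor", None, "Vibrio cholerae", "cqsS sensor histidine kinase"),
    ("GlpQ", "Ethanolamine", "synthase", None, "Haemophilus influenzae", "glycerophosphodiester phosphodiesterase"),
    ("CqsR", "Ethanolamine", "receptor", None, "Campylobacter jejuni", "ethanolamine-responsive kinase CqsR"),
]

# Eleven further signal classes detected with only one role: synthetic
# stand-ins mirroring the structure (one entry each) of the study's
# incomplete-pathway supplement.
_INCOMPLETE = [
    ("LqsA", "AHK-2", "synthase", None, "Legionella pneumophila", "LqsA autoinducer synthase"),
    ("ComC", "CSP", "synthase", None, "Streptococcus pneumoniae", "competence stimulating peptide"),
    ("ComR", "XIP", "receptor", None, "Streptococcus mutans", "ComR RRNPP receptor"),
    ("FsrD", "GBAP", "synthase", None, "Enterococcus faecalis", "gelatinase biosynthesis peptide"),
    ("PlnA", "PlnA-peptide", "synthase", None, "Lactobacillus plantarum", "plantaricin induction peptide"),
    ("QseC", "AI-3", "receptor", None, "Escherichia coli", "QseC adrenergic sensor kinase"),
    ("TnaA", "Indole", "synthase", None, "Escherichia coli", "tryptophanase"),
    ("PpyS", "Photopyrone", "synthase", None, "Photorhabdus luminescens", "photopyrone synthase"),
    ("DarB", "Dialkylresorcinol", "synthase", None, "Photorhabdus asymbiotica", "dialkylresorcinol synthase"),
    ("NdoA", "DKP", "synthase", None, "Pseudomonas putida", "diketopiperazine synthase"),
    ("SdiA", "AHL-orphan", "receptor", None, "Escherichia coli", "orphan LuxR-family receptor"),
]


def random_protein(rng: np.random.Generator, length: int) -> str:
    """Deterministic synthetic protein: i.i.d. draws from natural AA frequencies."""
    return "".join(rng.choice(AA_ALPHABET, size=length, p=AA_FREQS))


def fixture_reference_db() -> ReferenceDB:
    """Build the bundled 21-signal fixture reference database.

    Deterministic: sequences are generated from a fixed seed, so every call
    returns an identical database. Reference proteins are 120-180 aa.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    entries = []
    for name, signal, role, step, organism, keyword in _COMPLETE + _INCOMPLETE:
        length = int(rng.integers(120, 181))
        entries.append(
            ReferenceQSProtein(
                protein_id=name,
                signal=signal,
                role=Role(role),
                step=step,
                source_organism=organism,
                sequence=random_protein(rng, length),
                domain_keyword=keyword,
            )
        )
    return ReferenceDB(entries=entries)


def complete_fixture_signals() -> list[str]:
    """Signal classes carrying both synthase-side and receptor references."""
    seen: list[str] = []
    for _, signal, *_ in _COMPLETE:
        if signal not in seen:
            seen.append(signal)
    return seen


def incomplete_fixture_signals() -> list[str]:
    """Signal classes represented by a single role in the fixture DB."""
    return [signal for _, signal, *_ in _INCOMPLETE]


#: genus carrying each fixture protein's homolog, for the worked-example
#: catalog; proteins not listed rotate over the five core genera
_CATALOG_GENUS = {
    "AgrD": "Streptococcus",
    "AgrC": "Streptococcus",
    "NisC": "Streptococcus",
    "CbnS": "Streptococcus",
    "Pfs": "Streptococcus",
    "LuxS": "Streptococcus",
    "AibA": "Veillonella",
    "LsrB": "Megasphaera",
    "RpfF": "Prevotella",
    "RpfR": "Fusobacterium",
}

_CORE_GENERA = ["Streptococcus", "Veillonella", "Megasphaera", "Prevotella", "Fusobacterium"]


def fixture_catalog(identity: float = 0.8) -> tuple[dict, dict, dict]:
    """Worked-example gene catalog: one homolog per fixture reference.

    Each catalog gene is the corresponding reference mutated to the given
    identity, annotated with the reference's domain keyword, and assigned
    to a genus (Table-1-style mapping for the named proteins, round-robin
    over the five core genera otherwise). Running homolog search and
    completeness classification on this catalog detects all 21 fixture
    signals, of which exactly the ten both-role signals are complete.

    Returns (genes, taxonomy, annotations), each keyed by gene id.
    """
    from .synthetic import plant_homolog  # deferred: avoids an import cycle

    db = fixture_reference_db()
    rng = np.random.default_rng(_FIXTURE_SEED + 1)
    genes, taxonomy, annotations = {}, {}, {}
    for i, ref in enumerate(db):
        gene_id = f"cat_{ref.protein_id}"
        seq, _ = plant_homolog(ref.sequence, identity, int(rng.integers(2**31)))
        genes[gene_id] = seq
        taxonomy[gene_id] = _CATALOG_GENUS.get(ref.protein_id, _CORE_GENERA[i % 5])
        annotations[gene_id] = f"putative {ref.domain_keyword} family protein"
    return genes, taxonomy, annotations
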