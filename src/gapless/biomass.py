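"""Biomass-equation construction from measured macromolecular composition.

The biomass pseudo-reaction consumes precursors in the molar ratios
implied by the measured cell composition (percent w/w of cell dry
weight) and its flux carries the growth rate.  Polymerized components
(protein, DNA, RNA, glucan, chitin) contribute at their *residue* molar
mass — the monomer mass minus one water released on bond formation —
so that the coefficients close the measured mass exactly:

    coefficient [mmol/g CDW] = (weight% / 100) / (M_monomer - M_water) * 1000

Fatty acids enter at their free-acid molar mass from the summed
esterified and free pools.  The glycerolipid headgroup demand
(glycerol-3-phosphate, phosphoethanolamine, phosphocholine) is solved
from the measured TAG:PE:PC weight ratio together with the fatty-acid
ester mole balance (3 esters per triacylglycerol, 2 per phospholipid).
Maintenance coefficients (ATP/ADP/water/phosphate, sulfate, riboflavin)
are copied from the S. cerevisiae iMM904 biomass equation, and trace
amounts of ubiquitous cofactors are added so the model must be able to
synthesize them.

Sign convention: consumed species negative, released species (ADP,
phosphate) positive; ash is not part of the equation.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from gapless.chem_core import Formula, molar_mass, parse_formula

__all__ = [
    "BiomassComposition",
    "BiomassEquation",
    "BiomassConfig",
    "polymer_coefficient",
    "amino_acid_coefficients",
    "dna_coefficients",
    "rna_coefficients",
    "lipid_apportionment",
    "assemble_equation",
    "load_composition",
    "load_config",
    "default_composition",
    "default_config",
    "AMINO_ACIDS",
    "FATTY_ACIDS",
    "WATER",
]

WATER = parse_formula("H2O")

#: Canonical amino acids: key -> (KEGG id, name, formula).
AMINO_ACIDS: dict[str, tuple[str, str, str]] = {
    "Ala": ("C00133", "Alanine", "C3H7NO2"),
    "Arg": ("C00062", "Arginine", "C6H14N4O2"),
    "Asn": ("C00152", "Asparagine", "C4H8N2O3"),
    "Asp": ("C00049", "Aspartate", "C4H7NO4"),
    "Cys": ("C00097", "Cysteine", "C3H7NO2S"),
    "Gln": ("C00064", "Glutamine", "C5H10N2O3"),
    "Glu": ("C00025", "Glutamate", "C5H9NO4"),
    "Gly": ("C00037", "Glycine", "C2H5NO2"),
    "His": ("C00135", "Histidine", "C6H9N3O2"),
    "Ile": ("C00407", "Isoleucine", "C6H13NO2"),
    "Leu": ("C00123", "Leucine", "C6H13NO2"),
    "Lys": ("C00047", "Lysine", "C6H14N2O2"),
    "Met": ("C00073", "Methionine", "C5H11NO2S"),
    "Phe": ("C00079", "Phenylalanine", "C9H11NO2"),
    "Pro": ("C00148", "Proline", "C5H9NO2"),
    "Ser": ("C00065", "Serine", "C3H7NO3"),
    "Thr": ("C00188", "Threonine", "C4H9NO3"),
    "Trp": ("C00078", "Tryptophan", "C11H12N2O2"),
    "Tyr": ("C00082", "Tyrosine", "C9H11NO3"),
    "Val": ("C00183", "Valine", "C5H11NO2"),
}

#: Fatty acids: key -> (KEGG id, name, formula).
FATTY_ACIDS: dict[str, tuple[str, str, str]] = {
    "myristic": ("C06424", "Myristic acid", "C14H28O2"),
    "palmitic": ("C00249", "Palmitic acid", "C16H32O2"),
    "palmitoleic": ("C08362", "Palmitoleic acid", "C16H30O2"),
    "stearic": ("C01530", "Stearic acid", "C18H36O2"),
    "oleic": ("C00712", "Oleic acid", "C18H34O2"),
    "linoleic": ("C01595", "Linoleic acid", "C18H32O2"),
    "alpha_linolenic": ("C06427", "alpha-Linolenic acid", "C18H30O2"),
    "arachidic": ("C00219", "Arachidic acid", "C20H40O2"),
    "lignoceric": ("C08320", "Lignoceric acid", "C24H48O2"),
}

ERGOSTEROL = ("C01694", "Ergosterol", "C28H44O")

DEOXYRIBONUCLEOTIDES = {
    "dA": ("C00360", "dAMP", "C10H14N5O6P"),
    "dC": ("C00239", "dCMP", "C9H14N3O7P"),
    "dG": ("C00362", "dGMP", "C10H14N5O7P"),
    "dT": ("C00364", "dTMP", "C10H15N2O8P"),
}

RIBONUCLEOTIDES = {
    "A": ("C00020", "AMP", "C10H14N5O7P"),
    "C": ("C00055", "CMP", "C9H14N3O8P"),
    "G": ("C00144", "GMP", "C10H14N5O8P"),
    "U": ("C00105", "UMP", "C9H13N2O9P"),
}

GLUCOSE = ("C00031", "D-Glucose", "C6H12O6")
NAG = ("C00140", "N-Acetyl-D-glucosamine", "C8H15NO6")
GLYCEROL = parse_formula("C3H8O3")
HEADGROUPS = {
    "glycerol_3_p": ("C00093", "Glycerol-3-phosphate", "C3H9O6P"),
    "phosphoethanolamine": ("C00346", "Phosphoethanolamine", "C2H8NO4P"),
    "phosphocholine": ("C00588", "Phosphocholine", "C5H14NO4P"),
}


def _mass(formula_text: str) -> float:
    return molar_mass(parse_formula(formula_text))


@dataclass
class BiomassComposition:
    """Measured macromolecular composition, % w/w of cell dry weight."""

    protein_pct: float
    aa_weight_pct: dict[str, float]
    carbohydrate_pct: float
    chitin_pct: float
    rna_pct: float
    dna_pct: float
    gc_content: float
    rna_base_fractions: dict[str, float]
    esterified_fa_pct: dict[str, float] = field(default_factory=dict)
    free_fa_pct: dict[str, float] = field(default_factory=dict)
    ergosterol_pct: float = 0.0
    lipid_class_weight_ratio: tuple[float, float, float] = (0.52, 0.16, 0.32)
    ash_pct: float = 0.0

    def __post_init__(self) -> None:
        for label, value in (
            ("protein_pct", self.protein_pct),
            ("carbohydrate_pct", self.carbohydrate_pct),
            ("chitin_pct", self.chitin_pct),
            ("rna_pct", self.rna_pct),
            ("dna_pct", self.dna_pct),
            ("ergosterol_pct", self.ergosterol_pct),
            ("ash_pct", self.ash_pct),
        ):
            if value < 0:
                raise ValueError(f"{label} negative: {value}")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        unknown = set(self.aa_weight_pct) - set(AMINO_ACIDS)
        if unknown:
            raise ValueError(f"unknown amino-acid keys: {sorted(unknown)}")
        aa_sum = sum(self.aa_weight_pct.values())
        if self.aa_weight_pct and abs(aa_sum - self.protein_pct) > 0.1:
            raise ValueError(
                f"amino-acid percentages sum to {aa_sum}, protein is {self.protein_pct}"
            )
        if self.rna_base_fractions:
            total = sum(self.rna_base_fractions.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"RNA base fractions sum to {total}, expected 1")

    @property
    def glucan_pct(self) -> float:
        """Carbohydrate other than chitin, modelled as glucose polymer."""
        return self.carbohydrate_pct - self.chitin_pct


@dataclass
class BiomassConfig:
    """Copied/maintenance coefficients and trace-cofactor settings."""

    copied_coefficients: dict[str, float]
    trace_compounds: dict[str, str]  # KEGG id -> name
    trace_amount: float = 1e-6
    #: Measured fatty-acid-ester pool; None -> computed from composition.
    ester_pool_mmol: float | None = None
    mean_ester_mw: float | None = None


def polymer_coefficient(
    weight_pct: float, monomer: Formula, condensation_loss: Formula = WATER
) -> float:
    """mmol of monomer per g CDW inside a polymer of measured weight%.

    The monomer contributes its residue mass (monomer minus the
    condensation loss, water for all biological polymers here).
    """
    residue = molar_mass(monomer) - molar_mass(condensation_loss)
    if residue <= 0:
        raise ValueError("condensation loss at least as heavy as the monomer")
    return (weight_pct / 100.0) / residue * 1000.0


def amino_acid_coefficients(composition: BiomassComposition) -> dict[str, float]:
    """Per-amino-acid mmol/g CDW from the protein weight breakdown."""
    out: dict[str, float] = {}
    for key, pct in composition.aa_weight_pct.items():
        kegg, _, formula = AMINO_ACIDS[key]
        out[kegg] = polymer_coefficient(pct, parse_formula(formula))
    return out


def dna_coefficients(dna_pct: float, gc_content: float) -> dict[str, float]:
    """Deoxyribonucleotide mmol/g CDW from DNA weight% and genome GC.

    Base fractions follow Chargaff pairing: dG = dC = GC/2 and
    dA = dT = (1 - GC)/2; the total residue amount is the DNA mass over
    the composition-weighted mean residue (dNMP - water) mass.
    """
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must be in [0, 1]")
    fractions = {
        "dA": (1 - gc_content) / 2,
        "dT": (1 - gc_content) / 2,
        "dG": gc_content / 2,
        "dC": gc_content / 2,
    }
    return _nucleotide_coefficients(dna_pct, fractions, DEOXYRIBONUCLEOTIDES)


def rna_coefficients(
    rna_pct: float, base_fractions: Mapping[str, float]
) -> dict[str, float]:
    """Ribonucleotide mmol/g CDW from RNA weight% and base molar fractions."""
    total = sum(base_fractions.values())
    if base_fractions and abs(total - 1.0) > 1e-6:
        raise ValueError(f"base fractions sum to {total}, expected 1")
    return _nucleotide_coefficients(rna_pct, base_fractions, RIBONUCLEOTIDES)


def _nucleotide_coefficients(
    weight_pct: float,
    fractions: Mapping[str, float],
    table: Mapping[str, tuple[str, str, str]],
) -> dict[str, float]:
    if weight_pct == 0:
        return {table[k][0]: 0.0 for k in fractions}
    water = molar_mass(WATER)
    mean_residue = sum(
        frac * (_mass(table[key][2]) - water) for key, frac in fractions.items()
    )
    total_mmol = (weight_pct / 100.0) / mean_residue * 1000.0
    return {table[key][0]: frac * total_mmol for key, frac in fractions.items()}


def lipid_apportionment(
    esterified_fa_pct: Mapping[str, float],
    free_fa_pct: Mapping[str, float],
    lipid_class_weight_ratio: tuple[float, float, float],
    ergosterol_pct: float,
    ester_pool_mmol: float | None = None,
    mean_ester_mw: float | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Fatty-acid, sterol and glycerolipid-headgroup coefficients.

    Per-fatty-acid coefficients use the summed esterified + free mass
    over the free-acid molar mass; ergosterol likewise.  The TAG:PE:PC
    class amounts are solved from their weight ratio together with the
    ester mole balance (3 TAG + 2 PE + 2 PC esters = total ester pool),
    and each class demands one headgroup: glycerol 3-phosphate for every
    glycerolipid, plus phosphoethanolamine (PE) or phosphocholine (PC).

    ``ester_pool_mmol``/``mean_ester_mw`` override the pool size and
    the mean fatty-acid molar mass used for class molecular weights;
    when absent both are computed from the esterified masses.
    Returns ``(fatty_acid_and_sterol, headgroups)`` keyed by KEGG id.
    """
    water = molar_mass(WATER)
    fa_coeffs: dict[str, float] = {}
    for key, (kegg, _, formula) in FATTY_ACIDS.items():
        total_pct = esterified_fa_pct.get(key, 0.0) + free_fa_pct.get(key, 0.0)
        if total_pct:
            fa_coeffs[kegg] = (total_pct / 100.0) / _mass(formula) * 1000.0
    if ergosterol_pct:
        fa_coeffs[ERGOSTEROL[0]] = (ergosterol_pct / 100.0) / _mass(ERGOSTEROL[2]) * 1000.0

    ester_mass = sum(esterified_fa_pct.values()) / 100.0 * 1000.0  # mg/g CDW
    computed_pool = sum(
        (pct / 100.0) / _mass(FATTY_ACIDS[key][2]) * 1000.0
        for key, pct in esterified_fa_pct.items()
    )
    if computed_pool == 0:
        # nothing esterified was measured: no glycerolipids, no headgroups,
        # regardless of any configured pool override
        return fa_coeffs, {}
    pool = ester_pool_mmol if ester_pool_mmol is not None else computed_pool
    mw_est = (
        mean_ester_mw
        if mean_ester_mw is not None
        else (ester_mass / computed_pool if computed_pool else 0.0)
    )

    w_tag, w_pe, w_pc = lipid_class_weight_ratio
    if w_tag + w_pe + w_pc <= 0:
        raise ValueError("degenerate lipid class ratio with a nonzero ester pool")
    # Class molecular weights from the mean ester MW: each acyl ester
    # bond and the headgroup phosphoester each release one water.
    m_glycerol = molar_mass(GLYCEROL)
    m_tag = 3 * mw_est + m_glycerol - 3 * water
    m_pe = 2 * mw_est + m_glycerol - 2 * water + _mass(HEADGROUPS["phosphoethanolamine"][2]) - water
    m_pc = 2 * mw_est + m_glycerol - 2 * water + _mass(HEADGROUPS["phosphocholine"][2]) - water
    # Weight fractions scale a common factor W (total class mass):
    # esters per unit W = 3 w_tag/m_tag + 2 w_pe/m_pe + 2 w_pc/m_pc.
    esters_per_w = 3 * w_tag / m_tag + 2 * w_pe / m_pe + 2 * w_pc / m_pc
    total_w = pool / esters_per_w
    n_tag = w_tag * total_w / m_tag
    n_pe = w_pe * total_w / m_pe
    n_pc = w_pc * total_w / m_pc
    headgroups = {
        HEADGROUPS["glycerol_3_p"][0]: n_tag + n_pe + n_pc,
        HEADGROUPS["phosphoethanolamine"][0]: n_pe,
        HEADGROUPS["phosphocholine"][0]: n_pc,
    }
    return fa_coeffs, headgroups


@dataclass
class BiomassEquation:
    """Signed coefficient vector (mmol/g CDW) with per-entry provenance.

    Provenance tags follow the footnote scheme of the composition table:
    ``protein``, ``fatty-acid``, ``sterol``, ``headgroup``,
    ``carbohydrate``, ``dna``, ``rna``, ``copied``, ``trace``.
    """

    coefficients: dict[str, float]
    provenance: dict[str, str]
    names: dict[str, str] = field(default_factory=dict)

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        return {cid: round(c, ndigits) for cid, c in self.coefficients.items()}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["kegg_id", "name", "coefficient", "provenance"])
            for cid in sorted(self.coefficients):
                w.writerow(
                    [
                        cid,
                        self.names.get(cid, ""),
                        repr(self.coefficients[cid]),
                        self.provenance.get(cid, ""),
                    ]
                )


_NAMES = {
    **{kegg: name for kegg, name, _ in AMINO_ACIDS.values()},
    **{kegg: name for kegg, name, _ in FATTY_ACIDS.values()},
    **{kegg: name for kegg, name, _ in DEOXYRIBONUCLEOTIDES.values()},
    **{kegg: name for kegg, name, _ in RIBONUCLEOTIDES.values()},
    **{kegg: name for kegg, name, _ in HEADGROUPS.values()},
    ERGOSTEROL[0]: ERGOSTEROL[1],
    GLUCOSE[0]: GLUCOSE[1],
    NAG[0]: NAG[1],
}


def assemble_equation(
    composition: BiomassComposition, config: BiomassConfig
) -> BiomassEquation:
    """Merge all category computations into the final biomass equation.

    Consumption is negative; only the copied ADP and phosphate entries
    are positive.  Ash is excluded.  A compound appearing in more than
    one category is an assembly error.
    """
    coefficients: dict[str, float] = {}
    provenance: dict[str, str] = {}

    def put(cid: str, value: float, tag: str) -> None:
        if cid in coefficients:
            raise ValueError(f"compound {cid} assigned by both {provenance[cid]} and {tag}")
        coefficients[cid] = value
        provenance[cid] = tag

    for cid, value in amino_acid_coefficients(composition).items():
        put(cid, -value, "protein")

    fa, headgroups = lipid_apportionment(
        composition.esterified_fa_pct,
        composition.free_fa_pct,
        composition.lipid_class_weight_ratio,
        composition.ergosterol_pct,
        ester_pool_mmol=config.ester_pool_mmol,
        mean_ester_mw=config.mean_ester_mw,
    )
    for cid, value in fa.items():
        put(cid, -value, "sterol" if cid == ERGOSTEROL[0] else "fatty-acid")
    for cid, value in headgroups.items():
        put(cid, -value, "headgroup")

    if composition.glucan_pct:
        put(
            GLUCOSE[0],
            -polymer_coefficient(composition.glucan_pct, parse_formula(GLUCOSE[2])),
            "carbohydrate",
        )
    if composition.chitin_pct:
        put(
            NAG[0],
            -polymer_coefficient(composition.chitin_pct, parse_formula(NAG[2])),
            "carbohydrate",
        )

    for cid, value in dna_coefficients(composition.dna_pct, composition.gc_content).items():
        put(cid, -value, "dna")
    for cid, value in rna_coefficients(
        composition.rna_pct, composition.rna_base_fractions
    ).items():
        put(cid, -value, "rna")

    for cid, value in config.copied_coefficients.items():
        put(cid, value, "copied")  # already signed in the config
    for cid in config.trace_compounds:
        put(cid, -config.trace_amount, "trace")

    return BiomassEquation(coefficients, provenance, dict(_NAMES))


# -- packaged data -----------------------------------------------------------


def load_composition(path: str | Path) -> BiomassComposition:
    """Read a composition TSV with columns section, key, value."""
    sections: dict[str, dict[str, float]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            sections.setdefault(row["section"], {})[row["key"]] = float(row["value"])
    scalars = sections.get("total", {})
    ratio = sections.get("lipid_class_ratio", {})
    return BiomassComposition(
        protein_pct=scalars["protein"],
        aa_weight_pct=sections.get("amino_acid", {}),
        carbohydrate_pct=scalars["carbohydrate"],
        chitin_pct=scalars.get("chitin", 0.0),
        rna_pct=scalars["rna"],
        dna_pct=scalars["dna"],
        gc_content=scalars["gc_content"],
        rna_base_fractions=sections.get("rna_base_fraction", {}),
        esterified_fa_pct=sections.get("fatty_acid_ester", {}),
        free_fa_pct=sections.get("fatty_acid_free", {}),
        ergosterol_pct=scalars.get("ergosterol", 0.0),
        lipid_class_weight_ratio=(
            ratio.get("TAG", 0.52),
            ratio.get("PE", 0.16),
            ratio.get("PC", 0.32),
        ),
        ash_pct=scalars.get("ash", 0.0),
    )


def load_config(path: str | Path) -> BiomassConfig:
    payload = json.loads(Path(path).read_text())
    return BiomassConfig(
        copied_coefficients=payload["copied_coefficients"],
        trace_compounds=payload["trace_compounds"],
        trace_amount=payload.get("trace_amount", 1e-6),
        ester_pool_mmol=payload.get("ester_pool_mmol"),
        mean_ester_mw=payload.get("mean_ester_mw"),
    )


def _data_path(name: str) -> Path:
    return Path(resources.files("gapless").joinpath("data", name))


def default_composition() -> BiomassComposition:
    """The packaged measured composition of T. reesei mycelium."""
    return load_composition(_data_path("biomass_composition_treesei.tsv"))


def default_config() -> BiomassConfig:
    return load_config(_data_path("biomass_config.json"))
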