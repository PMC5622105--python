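"""Packaged fixtures: the printed liver-ECM abundance table and the printed
binding-rate parameters, plus helpers to turn them into model inputs.

The abundance fixture carries, per protein, the published molar
concentration in each treatment group together with the *printed* log2 fold
change; :func:`inconsistent_log2fc` identifies rows whose printed fold
change cannot be recomputed from the printed concentration cells (beyond
last-digit rounding), which includes every zero-floored row.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd
import yaml

from . import proteome
from .errors import ConfigurationError
from .kinetics import EquilibriumRelations, RatePair, Scenario, UM_TO_NM
from .proteome import AbundanceTable, ProteinRecord, molar_to_empai

_DATA = importlib.resources.files("ecmbind") / "data"

CONTROL = "control"
TREATMENT = "ccl4"


def _read_text(name: str) -> str:
    return (_DATA / name).read_text(encoding="utf-8")


def abundance_frame() -> pd.DataFrame:
    """Raw printed abundance fixture (µM per group + printed log2FC)."""
    import io

    return pd.read_csv(io.StringIO(_read_text("liver_ecm_abundance.tsv")), sep="\t")


def abundance_table() -> AbundanceTable:
    """The printed abundance fixture as an :class:`AbundanceTable`.

    The ``log2fc`` column is recomputed from the printed µM cells with the
    default 1e-5 µM zero floor; the printed values stay available in
    ``printed_log2fc``.
    """
    frame = abundance_frame().rename(columns={"conc_ccl4_uM": "conc_treatment_uM"})
    return AbundanceTable.from_concentrations(
        frame, control_group=CONTROL, treatment_group=TREATMENT
    )


def inconsistent_log2fc(tol: float = proteome.LOG2FC_REPORT_TOL) -> list[str]:
    """Protein ids whose printed log2FC disagrees with the printed µM cells
    by more than ``tol`` (all zero-floored rows fall in this set)."""
    table = abundance_table()
    df = table.data
    return df.loc[
        (df["printed_log2fc"] - df["log2fc"]).abs() > tol, "protein_id"
    ].tolist()


def rate_config() -> dict:
    return yaml.safe_load(_read_text("binding_rates.yaml"))


def binding_scenarios(
    groups: tuple[str, ...] = (TREATMENT, CONTROL),
    relations: EquilibriumRelations = EquilibriumRelations(),
    model: str = "aggregation",
) -> list[Scenario]:
    """The fixture ligand:receptor scenarios, one per pairing and group.

    Ligand totals come from the abundance fixture (µM × 1000 → nM); receptor
    totals and rate pairs from the printed parameter table.
    """
    cfg = rate_config()
    conc = abundance_frame().set_index("protein_id")
    scenarios = []
    for pairing in cfg["pairings"]:
        ligand = pairing["ligand"]
        receptor = pairing["receptor"]
        rp = cfg["rate_pairs"][pairing["rates"]]
        pair = RatePair(
            k_on_per_M_s=float(rp["k_on_per_M_s"]),
            k_off_per_s=float(rp["k_off_per_s"]),
        )
        receptor_total = float(cfg["receptors"][receptor]["total_nM"])
        for group in groups:
            col = {CONTROL: "conc_control_uM", TREATMENT: "conc_ccl4_uM"}.get(group)
            if col is None:
                raise ConfigurationError(f"fixture has no group {group!r}")
            ligand_um = float(conc.loc[ligand, col])
            scenarios.append(
                Scenario(
                    ligand=ligand,
                    receptor=receptor,
                    receptor_total_nM=receptor_total,
                    ligand_total_nM=ligand_um * UM_TO_NM,
                    rates=pair,
                    relations=relations,
                    model=model,
                    group=group,
                )
            )
    return scenarios


def fixture_protein_records(
    loading: float = proteome.DEFAULT_LOADING_UG_PER_UL,
) -> list[ProteinRecord]:
    """Record-format (pre-combined) view of the abundance fixture.

    Synthetic inversion: per-fraction emPAI scores are not published, so the
    combined emPAI is back-computed from the printed µM values via the
    algebraic inverse of the emPAI→molar conversion.  Useful for exercising
    the ingest path end-to-end against the printed table.
    """
    records = []
    for _, row in abundance_frame().iterrows():
        for group, col in ((CONTROL, "conc_control_uM"), (TREATMENT, "conc_ccl4_uM")):
            records.append(
                ProteinRecord(
                    protein_id=row["protein_id"],
                    go_accession=row["go_accession"],
                    mw_kda=float(row["mw_kda"]),
                    group=group,
                    fraction=proteome.COMBINED,
                    empai=molar_to_empai(float(row[col]), float(row["mw_kda"]), loading),
                )
            )
    return records
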