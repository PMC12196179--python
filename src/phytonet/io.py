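"""Plain-text I/O for every table the pipeline consumes or emits.

Formats are deliberately simple: CSV with documented headers for peak
tables, ladders, dose-response, events and docking grids; TSV for edge
lists (STRING 0-1000 integer scores or [0, 1] fractions, auto-detected
downstream) and compound-target mappings; GMT for annotation catalogs
(via :meth:`phytonet.enrichment.AnnotationCatalog`); SIF for network export.
"""
from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .druglikeness import CompoundDescriptor
from .exceptions import ParseError, ValidationError
from .gcms import AlkaneLadder, ChromatogramPeak
from .invitro import DoseResponse, FlowEventSet

__all__ = [
    "read_alkane_ladder", "write_alkane_ladder",
    "read_peak_table", "write_peak_table",
    "read_descriptors", "write_descriptors",
    "read_edge_list", "write_edge_list",
    "read_target_mapping", "write_target_mapping",
    "read_gene_list", "write_gene_list",
    "write_sif", "write_centralities",
    "read_dose_response", "write_dose_response",
    "read_flow_events", "write_flow_events",
    "read_docking_matrix", "write_docking_matrix",
]


# -- alkane ladders: CSV with columns carbon_number, rt ----------------------

def read_alkane_ladder(path) -> AlkaneLadder:
    df = pd.read_csv(path)
    missing = {"carbon_number", "rt"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: ladder CSV lacks columns {sorted(missing)}")
    return AlkaneLadder(tuple(df["carbon_number"].astype(int)),
                        tuple(df["rt"].astype(float)))


def write_alkane_ladder(ladder: AlkaneLadder, path) -> None:
    ladder.to_frame().to_csv(path, index=False)


# -- peak tables: CSV with peak_id, rt, name, chemical_class, area_pct,
#    optional ri_exp / ri_lit ------------------------------------------------

_PEAK_REQUIRED = ("peak_id", "rt", "name", "chemical_class", "area_pct")


def read_peak_table(path) -> list[ChromatogramPeak]:
    df = pd.read_csv(path)
    missing = set(_PEAK_REQUIRED) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: peak CSV lacks columns {sorted(missing)}")
    peaks = []
    for _, r in df.iterrows():
        peaks.append(ChromatogramPeak(
            peak_id=int(r["peak_id"]), rt=float(r["rt"]), name=str(r["name"]),
            chemical_class=str(r["chemical_class"]),
            area_pct=float(r["area_pct"]),
            ri_exp=float(r["ri_exp"]) if "ri_exp" in df.columns
            and pd.notna(r.get("ri_exp")) else None,
            ri_lit=float(r["ri_lit"]) if "ri_lit" in df.columns
            and pd.notna(r.get("ri_lit")) else None))
    return peaks


def write_peak_table(peaks, path) -> None:
    rows = [{"peak_id": p.peak_id, "rt": p.rt, "name": p.name,
             "chemical_class": p.chemical_class, "area_pct": p.area_pct,
             "ri_exp": p.ri_exp, "ri_lit": p.ri_lit} for p in peaks]
    pd.DataFrame(rows).to_csv(path, index=False)


# -- descriptor tables -------------------------------------------------------

_DESC_REQUIRED = ("name", "mw", "logp", "hbd", "hba", "bioavailability_score")


def read_descriptors(path) -> list[CompoundDescriptor]:
    df = pd.read_csv(path)
    missing = set(_DESC_REQUIRED) - set(df.columns)
    if missing:
        raise ParseError(
            f"{path}: descriptor CSV lacks columns {sorted(missing)}")
    return [CompoundDescriptor(
        name=str(r["name"]), mw=float(r["mw"]), logp=float(r["logp"]),
        hbd=int(r["hbd"]), hba=int(r["hba"]),
        bioavailability_score=float(r["bioavailability_score"]),
        smiles=str(r["smiles"]) if "smiles" in df.columns
        and pd.notna(r.get("smiles")) else None)
        for _, r in df.iterrows()]


def write_descriptors(descs, path) -> None:
    pd.DataFrame([{
        "name": d.name, "mw": d.mw, "logp": d.logp, "hbd": d.hbd,
        "hba": d.hba, "bioavailability_score": d.bioavailability_score,
        "smiles": d.smiles} for d in descs]).to_csv(path, index=False)


# -- edge lists: TSV "node1<TAB>node2<TAB>score" -----------------------------

def read_edge_list(path) -> list[tuple[str, str, float]]:
    """Whitespace/tab separated scored edge list; a header line whose third
    field is non-numeric is skipped. Malformed rows raise
    :class:`ParseError` with their line number."""
    rows: list[tuple[str, str, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"expected 'node1 node2 score', got {line!r}",
                                 line=lineno)
            try:
                score = float(parts[2])
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ParseError(f"non-numeric score {parts[2]!r}",
                                 line=lineno)
            rows.append((parts[0], parts[1], score))
    return rows


def write_edge_list(net: nx.Graph, path, string_dialect: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node1\tnode2\tscore\n")
        for u, v, d in net.edges(data=True):
            conf = d.get("confidence", 1.0)
            score = round(conf * 1000) if string_dialect else conf
            fh.write(f"{u}\t{v}\t{score}\n")


# -- target mappings and gene lists ------------------------------------------

def read_target_mapping(path) -> dict[str, set[str]]:
    """Two-column TSV compound<TAB>gene -> compound-to-target-set dict."""
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"expected 'compound<TAB>gene', got {line!r}",
                                 line=lineno)
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def write_target_mapping(mapping: dict[str, set[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for compound in sorted(mapping):
            for gene in sorted(mapping[compound]):
                fh.write(f"{compound}\t{gene}\n")


def read_gene_list(path) -> set[str]:
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh
                if line.strip() and not line.startswith("#")}


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


# -- network exports ---------------------------------------------------------

def write_sif(net: nx.Graph, path, interaction: str = "pp") -> None:
    """Simple-interaction-format export (node1 <interaction> node2)."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in net.edges:
            fh.write(f"{u}\t{interaction}\t{v}\n")


def write_centralities(table: pd.DataFrame, path) -> None:
    table.to_csv(path)


# -- dose-response -----------------------------------------------------------

def read_dose_response(path, cell_line: str | None = None) -> DoseResponse:
    """CSV with a ``concentration`` column plus one column per replicate."""
    df = pd.read_csv(path)
    if "concentration" not in df.columns:
        raise ParseError(f"{path}: needs a 'concentration' column")
    reps = [c for c in df.columns if c != "concentration"]
    if not reps:
        raise ParseError(f"{path}: needs at least one replicate column")
    return DoseResponse(df["concentration"].to_numpy(),
                        df[reps].to_numpy(), cell_line=cell_line)


def write_dose_response(dr: DoseResponse, path) -> None:
    dr.to_frame().to_csv(path, index=False)


# -- flow events -------------------------------------------------------------

def read_flow_events(path) -> FlowEventSet:
    """CSV with columns annexin, pi; gates are carried on a leading comment
    line ``# annexin_gate=<x> pi_gate=<y>`` (defaults 2.0/2.0)."""
    gates = {"annexin_gate": 2.0, "pi_gate": 2.0}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first.lstrip("#").split():
            if "=" in token:
                key, val = token.split("=", 1)
                if key in gates:
                    gates[key] = float(val)
    df = pd.read_csv(path, comment="#")
    missing = {"annexin", "pi"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: event CSV lacks columns {sorted(missing)}")
    return FlowEventSet(df[["annexin", "pi"]].to_numpy(), **gates)


def write_flow_events(events: FlowEventSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# annexin_gate={events.annexin_gate} "
                 f"pi_gate={events.pi_gate}\n")
        events.to_frame().to_csv(fh, index=False)


# -- docking matrices --------------------------------------------------------

def read_docking_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.size == 0:
        raise ValidationError(f"{path}: empty docking matrix")
    return df.astype(float)


def write_docking_matrix(m: pd.DataFrame, path) -> None:
    m.to_csv(path)
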