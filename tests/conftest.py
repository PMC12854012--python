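import numpy as np
import pandas as pd
import pytest

from clonebridge.datamodel import CellMeta, ContigRecord, ExpressionMatrix


@pytest.fixture
def airr_writer(tmp_path):
    """Write rows (dicts) as an AIRR TSV and return its path."""

    def write(rows, name="contigs.tsv"):
        cols = ["cell_id", "locus", "junction", "junction_aa", "v_call", "j_call", "productive"]
        path = tmp_path / name
        df = pd.DataFrame(rows)
        for c in cols:
            if c not in df.columns:
                df[c] = ""
        df[cols].to_csv(path, sep="\t", index=False)
        return path

    return write


@pytest.fixture
def tenx_writer(tmp_path):
    def write(rows, name="filtered_contig_annotations.csv"):
        cols = [
            "barcode",
            "chain",
            "cdr3_nt",
            "cdr3",
            "v_gene",
            "j_gene",
            "productive",
            "umis",
            "high_confidence",
        ]
        path = tmp_path / name
        df = pd.DataFrame(rows)
        for c in cols:
            if c not in df.columns:
                df[c] = ""
        df[cols].to_csv(path, index=False)
        return path

    return write


def make_contig(barcode, locus="TRB", cdr3_nt="TGTGCCAGC", cdr3_aa="CAS", v="TRBV2",
                j="TRBJ1-1", productive=True, umis=1):
    return ContigRecord(
        barcode=barcode, locus=locus, cdr3_nt=cdr3_nt, cdr3_aa=cdr3_aa,
        v_call=v, j_call=j, productive=productive, umis=umis,
    )


def make_meta(barcode, patient="P1", compartment="skin", lineage="CD8", cluster=None):
    return CellMeta(barcode=barcode, patient=patient, compartment=compartment,
                    lineage=lineage, cluster_id=cluster)


@pytest.fixture
def paired_cell_factory():
    """Build (contigs, meta) for cells given (barcode, compartment, tra_nt, trb_nt)."""

    def build(cells, patient="P1", lineage="CD8"):
        contigs, meta = [], []
        for bc, comp, tra, trb in cells:
            contigs.append(make_contig(bc, "TRA", tra, "C" + "A" * (len(tra) // 3 - 1), "TRAV1-2", "TRAJ12"))
            contigs.append(make_contig(bc, "TRB", trb, "C" + "S" * (len(trb) // 3 - 1), "TRBV2", "TRBJ1-1"))
            meta.append(make_meta(bc, patient=patient, compartment=comp, lineage=lineage))
        return contigs, meta

    return build


@pytest.fixture
def small_matrix():
    """5 genes x 6 cells with a clean A-vs-B shift in GENEA."""
    rng = np.random.default_rng(0)
    genes = ["GENEA", "GENEB", "GENEC", "GENED", "GENEE"]
    cells = [f"c{i}" for i in range(6)]
    values = rng.normal(1.0, 0.1, size=(5, 6))
    values[0, :3] += 2.0
    return ExpressionMatrix(genes=genes, cells=cells, values=np.clip(values, 0, None))
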