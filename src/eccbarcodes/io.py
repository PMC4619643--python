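"""File formats: alist-style matrices, barcode manifests, reports, demux.

A barcode design is persisted as three text files sharing a prefix:

* ``<prefix>.fasta``   — the barcodes; record id = sample ordinal, record
  description = the message symbols.
* ``<prefix>.tsv``     — sidecar table: sample id, barcode, message.
* ``<prefix>.json``    — everything needed to decode: the code (H and G for
  LDPC; generator polynomial and parameters for BCH), the interleaver
  permutation, the bit/base mapping and the chemistry constraints.

Parity-check matrices travel in a plain-text alist-style format (the sparse
format used by LDPC software) extended with a VALUES section carrying the
GF(4) entries.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .bch import BCHSpec, BitBaseMapping, bch_decode, seq_to_symbols, symbols_to_seq
from .ldpc_codec import BPDecoder
from .ldpc_design import LDPCCodeSpec, ParityCheckMatrix, generator_from_parity
from .pipeline import BarcodeSet, ChemistryConstraints, Interleaver, deinterleave

logger = logging.getLogger("eccbarcodes")

__all__ = [
    "write_alist",
    "read_alist",
    "write_manifest",
    "read_manifest",
    "write_report",
    "demultiplex",
]

UNASSIGNED = "UNASSIGNED"


# ---------------------------------------------------------------------------
# alist-style sparse matrices with a GF(4) values section


def write_alist(path, H: ParityCheckMatrix) -> None:
    M = H.entries
    m, n = M.shape
    cols = [np.nonzero(M[:, c])[0] + 1 for c in range(n)]
    rows = [np.nonzero(M[r, :])[0] + 1 for r in range(m)]
    lines = [
        f"{n} {m}",
        f"{max(len(c) for c in cols)} {max(len(r) for r in rows)}",
        " ".join(str(len(c)) for c in cols),
        " ".join(str(len(r)) for r in rows),
    ]
    lines += [" ".join(map(str, c)) for c in cols]
    lines += [" ".join(map(str, r)) for r in rows]
    lines.append("VALUES")
    for c in range(n):
        lines.append(" ".join(str(int(M[r - 1, c])) for r in cols[c]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_alist(path) -> ParityCheckMatrix:
    raw = Path(path).read_text().splitlines()
    try:
        n, m = map(int, raw[0].split())
        col_deg = list(map(int, raw[2].split()))
        cols = [list(map(int, raw[4 + c].split())) for c in range(n)]
        vi = raw.index("VALUES")
        vals = [list(map(int, raw[vi + 1 + c].split())) for c in range(n)]
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: malformed alist file ({exc})") from exc
    H = np.zeros((m, n), dtype=np.uint8)
    for c in range(n):
        if len(cols[c]) != col_deg[c] or len(vals[c]) != col_deg[c]:
            raise ValueError(f"{path}: column {c + 1} degree mismatch")
        for r, v in zip(cols[c], vals[c]):
            H[r - 1, c] = v
    return ParityCheckMatrix(H, j=col_deg[0])


# ---------------------------------------------------------------------------
# manifests


def _code_to_json(spec) -> dict:
    if isinstance(spec, LDPCCodeSpec):
        return {
            "type": "ldpc",
            "H": spec.H.entries.tolist(),
            "j": spec.H.j,
            "G": spec.G.tolist(),
        }
    if isinstance(spec, BCHSpec):
        return {
            "type": "bch",
            "n": spec.n,
            "k": spec.k,
            "t": spec.t,
            "s": spec.s,
            "generator": spec.generator.tolist(),
            "m": spec.m,
            "mapping": spec.mapping.order,
        }
    raise TypeError(f"unsupported code spec {type(spec).__name__}")


def _code_from_json(d: dict):
    if d["type"] == "ldpc":
        H = ParityCheckMatrix(np.array(d["H"], dtype=np.uint8), j=d["j"])
        spec = generator_from_parity(H)
        if spec.G.tolist() != d["G"]:  # keep the stored G authoritative
            spec = LDPCCodeSpec(H=H, G=np.array(d["G"], dtype=np.uint8))
        return spec
    if d["type"] == "bch":
        return BCHSpec(
            n=d["n"], k=d["k"], t=d["t"], s=d["s"],
            generator=np.array(d["generator"], dtype=np.uint8), m=d["m"],
            mapping=BitBaseMapping(d["mapping"]),
        )
    raise ValueError(f"unknown code type {d['type']!r}")


def write_manifest(prefix, bset: BarcodeSet) -> dict[str, Path]:
    """Write FASTA + TSV + JSON for a barcode set; returns the paths."""
    prefix = Path(prefix)
    paths = {
        "fasta": prefix.with_suffix(".fasta"),
        "tsv": prefix.with_suffix(".tsv"),
        "json": prefix.with_suffix(".json"),
    }
    records = [
        SeqRecord(
            Seq(symbols_to_seq(bc)),
            id=str(i),
            description=" ".join(map(str, msg.tolist())),
        )
        for i, (bc, msg) in enumerate(zip(bset.barcodes, bset.messages))
    ]
    SeqIO.write(records, paths["fasta"], "fasta")
    pd.DataFrame(
        {
            "sample_id": np.arange(bset.M),
            "barcode": bset.sequences(),
            "message": [" ".join(map(str, m.tolist())) for m in bset.messages],
        }
    ).to_csv(paths["tsv"], sep="\t", index=False)
    doc = {
        "code": _code_to_json(bset.code_spec),
        "interleaver": {
            "permutation": bset.interleaver.permutation.tolist(),
            "spread": bset.interleaver.spread,
        },
        "constraints": {
            "max_homopolymer_run": bset.constraints.max_homopolymer_run,
            "gc_min": bset.constraints.gc_min,
            "gc_max": bset.constraints.gc_max,
        },
        "mode": bset.mode,
        "total_messages": bset.total_messages,
        "M": bset.M,
        "N": bset.N,
        "B": bset.B,
    }
    paths["json"].write_text(json.dumps(doc, indent=1))
    return paths


def read_manifest(json_path) -> BarcodeSet:
    json_path = Path(json_path)
    doc = json.loads(json_path.read_text())
    spec = _code_from_json(doc["code"])
    ivl = Interleaver(
        permutation=np.array(doc["interleaver"]["permutation"]),
        spread=doc["interleaver"]["spread"],
    )
    constraints = ChemistryConstraints(**doc["constraints"])
    df = pd.read_csv(json_path.with_suffix(".tsv"), sep="\t")
    barcodes = np.stack([seq_to_symbols(b) for b in df["barcode"]])
    messages = np.stack(
        [np.array(str(m).split(), dtype=np.uint8) for m in df["message"]]
    )
    codewords = deinterleave(barcodes, ivl)
    return BarcodeSet(
        barcodes=barcodes,
        codewords=codewords,
        messages=messages,
        code_spec=spec,
        interleaver=ivl,
        constraints=constraints,
        mode=doc["mode"],
        total_messages=doc["total_messages"],
    )


def write_report(path, rows: list[dict]) -> None:
    """Rectangular TSV report with full-precision numeric round-trip."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# demultiplexing


def demultiplex(
    bset: BarcodeSet,
    reads,
    out,
    p_s: float = 0.01,
    offset: int = 0,
    max_iterations: int = 50,
) -> dict:
    """Assign FASTQ reads to samples through the manifest's decoder.

    The barcode region (``offset`` .. ``offset + N``) of each read is
    deinterleaved and decoded; a read is assigned only when the decode
    succeeds *and* the decoded word maps to a manifest barcode — decode
    failures are counted as read losses, never assigned.  Returns summary
    counts; per-read assignments go to ``out`` as TSV.
    """
    N = bset.N
    spec = bset.code_spec
    if isinstance(spec, LDPCCodeSpec):
        decoder = BPDecoder(spec, p_s, max_iterations)
        lookup = {bytes(cw.tobytes()): i for i, cw in enumerate(bset.codewords)}
    elif isinstance(spec, BCHSpec):
        decoder = None
        lookup = {bytes(msg.tobytes()): i for i, msg in enumerate(bset.messages)}
    else:
        raise ValueError("manifest has no decodable code specification")

    summary = {
        "total": 0, "assigned": 0, "unassigned": 0,
        "decode_failure": 0, "not_in_manifest": 0,
        "too_short": 0, "malformed": 0,
        "per_sample": {},
    }
    rows = []

    def handle(read_id: str, seq: str):
        summary["total"] += 1
        region = seq[offset : offset + N].upper()
        if len(region) < N or any(b not in "ACGT" for b in region):
            summary["too_short"] += 1
            summary["unassigned"] += 1
            rows.append((read_id, region, UNASSIGNED, "decode-failure", 0))
            return
        obs = seq_to_symbols(region)
        inner = deinterleave(obs, bset.interleaver)
        if decoder is not None:
            words, success, iters = decoder.decode_batch(inner[None, :])
            ok, key, it = bool(success[0]), bytes(words[0].tobytes()), int(iters[0])
        else:
            outcome = bch_decode(spec, inner)
            ok = outcome.success
            key = bytes(outcome.word.tobytes()) if ok else b""
            it = outcome.iterations_used
        if not ok:
            summary["decode_failure"] += 1
            summary["unassigned"] += 1
            rows.append((read_id, region, UNASSIGNED, "decode-failure", it))
            return
        sample = lookup.get(key)
        if sample is None:
            summary["not_in_manifest"] += 1
            summary["unassigned"] += 1
            rows.append((read_id, region, UNASSIGNED, "correct-format", it))
            return
        summary["assigned"] += 1
        key_s = str(sample)
        summary["per_sample"][key_s] = summary["per_sample"].get(key_s, 0) + 1
        rows.append((read_id, region, sample, "correct-format", it))

    handle_path = isinstance(reads, (str, Path))
    fh = open(reads) if handle_path else reads
    try:
        iterator = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, _qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                summary["malformed"] += 1
                logger.warning("malformed FASTQ record skipped: %s", exc)
                break  # the 4-line frame is lost; stop rather than mis-parse
            handle(title.split()[0], seq)
    finally:
        if handle_path:
            fh.close()

    pd.DataFrame(
        rows,
        columns=["read_id", "observed_barcode", "assignment", "status",
                 "decoder_iterations"],
    ).to_csv(out, sep="\t", index=False)
    return summary
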