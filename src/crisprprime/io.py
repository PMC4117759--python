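"""Readers and writers for the standard formats used by the pipeline.

FASTA goes through Bio.SeqIO; tables are plain TSV via pandas; protospacer
intervals are additionally emitted as BED (0-based half-open, strand in
column 6); configuration is YAML.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mapping import ProtospacerHit
from .seq import CircularSequence
from .simulate import CRISPRArrayModel, PrimedSite


def read_plasmid(path, circular: bool = True) -> CircularSequence:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected a single FASTA record in {path}, found {len(records)}")
    rec = records[0]
    return CircularSequence(id=rec.id, seq=str(rec.seq), circular=circular)


def write_fasta(records, path) -> None:
    out = []
    for rec in records:
        if isinstance(rec, SeqRecord):
            out.append(rec)
        elif isinstance(rec, CircularSequence):
            out.append(SeqRecord(Seq(rec.seq), id=rec.id, description=""))
        else:
            rid, seq = rec
            out.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(out, str(path), "fasta")


def read_fasta(path):
    return list(SeqIO.parse(str(path), "fasta"))


def hits_to_frame(hits: list[ProtospacerHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "hit_id": h.hit_id,
                "plasmid_id": h.plasmid_id,
                "strand": h.strand,
                "start": h.start,
                "end": h.end,
                "length": h.length,
                "seq": h.seq,
                "flank5": h.flank5,
                "flank3": h.flank3,
                "pam": h.pam,
                "pam_class": h.pam_class,
                "mismatches": h.mismatches,
                "ambiguous": h.ambiguous,
                "note": h.note,
            }
            for h in hits
        ]
    )


def write_bed(hits: list[ProtospacerHit], path, L: int | None = None) -> None:
    """Protospacer intervals as BED6.

    Origin-spanning intervals (``end > L``) are reduced so BED consumers see
    in-range coordinates; the raw half-open pair is preserved in the TSV.
    """
    lines = []
    for h in hits:
        name = h.hit_id or h.seq[:8]
        if L is not None and h.end > L:
            # a BED interval cannot wrap: emit the two arcs of the split interval
            lines.append(f"{h.plasmid_id}\t{h.start}\t{L}\t{name}/1\t{h.mismatches}\t{h.strand}")
            lines.append(f"{h.plasmid_id}\t0\t{h.end % L}\t{name}/2\t{h.mismatches}\t{h.strand}")
        else:
            lines.append(f"{h.plasmid_id}\t{h.start}\t{h.end}\t{name}\t{h.mismatches}\t{h.strand}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def write_array_models(models: dict[str, CRISPRArrayModel], path) -> None:
    dump_yaml(
        {
            "arrays": [
                {
                    "array_id": m.array_id,
                    "repeat_consensus": m.repeat_consensus,
                    "wt_spacers": list(m.wt_spacers),
                }
                for m in models.values()
            ]
        },
        path,
    )


def read_array_models(path) -> dict[str, CRISPRArrayModel]:
    data = load_yaml(path)
    models = {}
    for entry in data["arrays"]:
        m = CRISPRArrayModel(
            array_id=entry["array_id"],
            repeat_consensus=entry["repeat_consensus"],
            wt_spacers=list(entry["wt_spacers"]),
        )
        models[m.array_id] = m
    return models


def write_primed_site(site: PrimedSite, path) -> None:
    dump_yaml(
        {
            "spacer": site.priming_spacer_seq,
            "pam_variant": site.pam_variant,
            "strand": site.protospacer.strand,
            "start": site.protospacer.start,
        },
        path,
    )


def read_primed_site_spec(path) -> dict:
    """Primed-site YAML: at least ``spacer`` and ``pam_variant``."""
    spec = load_yaml(path)
    if "spacer" not in spec or "pam_variant" not in spec:
        raise ValueError("primed-site spec needs 'spacer' and 'pam_variant'")
    return spec
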