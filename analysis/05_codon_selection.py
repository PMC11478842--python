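#!/usr/bin/env python
"""Codon usage and selection screen: RSCU / amino-acid profile of the
target accession, and counting-method Ka/Ks of every protein-coding gene
against the reference, with selection classing (>1 positive, =1 neutral,
<1 purifying).

Writes results/rscu.tsv and results/kaks.tsv.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, TARGET_SPECIES, ensure_dirs, study_dataset

from plastomarker.codon import kaks_ng86, rscu


def extract_pair(ds, gene_feature, ref_acc, other_acc):
    """Codon-aligned CDS pair via the alignment columns of the reference
    gene's exonic blocks."""
    aln = ds.alignment
    cols = np.concatenate([
        aln.columns_of_ref_interval(s, e) for s, e in gene_feature.parts
    ])
    a = aln.row(ref_acc)[cols].tobytes().decode()
    b = aln.row(other_acc)[cols].tobytes().decode()
    if len(a) % 3:
        return None
    return a, b


def main():
    ensure_dirs()
    ds = study_dataset()
    aln = ds.alignment
    ref = aln.reference_id
    target_acc = f"{TARGET_SPECIES}_01"

    rec = ds.records[target_acc]
    cds = ["".join(rec.sequence[s:e] for s, e in gf.parts)
           for gf in rec.features if gf.kind == "CDS"]
    table = rscu(cds)
    pd.DataFrame(
        [{"codon": c, "count": table.codon_counts[c],
          "rscu": round(v, 4)} for c, v in sorted(table.rscu.items())]
    ).to_csv(RESULTS / "rscu.tsv", sep="\t", index=False)

    rows = []
    ref_rec = ds.records[ref]
    for gf in ref_rec.features:
        if gf.kind != "CDS":
            continue
        for acc in aln.ids:
            if acc == ref:
                continue
            pair = extract_pair(ds, gf, ref, acc)
            if pair is None:
                continue
            try:
                r = kaks_ng86(*pair, gene=gf.name)
            except ValueError:
                continue
            rows.append({"gene": gf.name, "accession": acc,
                         "ka": round(r.ka, 5), "ks": round(r.ks, 5),
                         "ratio": round(r.ratio, 4),
                         "class": r.selection_class})
    kaks = pd.DataFrame(rows).drop_duplicates(["gene", "accession"])
    kaks.to_csv(RESULTS / "kaks.tsv", sep="\t", index=False)

    at3 = table.third_position_composition
    print(f"third-position A+T: {at3['A'] + at3['T']:.2f}")
    defined = kaks[kaks["class"] != "undefined"]
    print(f"Ka/Ks computed for {kaks.gene.nunique()} genes x "
          f"{kaks.accession.nunique()} accessions; class counts: "
          f"{defined['class'].value_counts().to_dict()}")


if __name__ == "__main__":
    main()
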