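#!/usr/bin/env python
"""The headline procedure: find SNP columns diagnostic for the target
species, design 3'-anchored allele-specific primer pairs plus a conserved
control pair, and validate both by in-silico PCR on every genome.

Writes results/diagnostic_snps.tsv, results/primers.tsv and
results/amplification_matrix.tsv.
"""

import pandas as pd

from _common import RESULTS, TARGET_SPECIES, ensure_dirs, study_dataset

from plastomarker import barcode as bc


def main():
    ensure_dirs()
    ds = study_dataset()
    aln = ds.alignment

    snps = bc.find_diagnostic_snps(aln, TARGET_SPECIES)
    pd.DataFrame([s.__dict__ for s in snps]).to_csv(
        RESULTS / "diagnostic_snps.tsv", sep="\t", index=False
    )
    pairs = bc.design_diagnostic_pair(aln, snps)
    control = bc.design_control_pair(aln)
    chosen = [pairs[0], control] if pairs else [control]

    prows, mrows = [], []
    for p in chosen:
        prows.append({
            "role": p.role, "forward": p.forward, "reverse": p.reverse,
            "product_size": p.product_size,
            "tm_forward": round(p.tm_forward, 2),
            "tm_reverse": round(p.tm_reverse, 2),
            "gc_forward": round(p.gc_forward, 3),
            "gc_reverse": round(p.gc_reverse, 3),
        })
        for acc, rec in ds.records.items():
            amps = bc.in_silico_pcr(rec, p)
            mrows.append({
                "role": p.role, "accession": acc,
                "species": aln.species_of[acc], "amplicons": len(amps),
                "sizes": ";".join(str(a.size) for a in amps),
            })
    pd.DataFrame(prows).to_csv(RESULTS / "primers.tsv", sep="\t",
                               index=False)
    matrix = pd.DataFrame(mrows)
    matrix.to_csv(RESULTS / "amplification_matrix.tsv", sep="\t",
                  index=False)

    print(f"{len(snps)} diagnostic SNP columns for {TARGET_SPECIES} "
          f"(flank conservation >= 0.8)")
    if pairs:
        p = pairs[0]
        print(f"diagnostic pair: {p.forward} / {p.reverse}, product "
              f"{p.product_size} bp; control product "
              f"{control.product_size} bp")
    diag = matrix[matrix.role == "diagnostic"]
    on = diag[diag.species == TARGET_SPECIES].amplicons
    off = diag[diag.species != TARGET_SPECIES].amplicons
    ctrl = matrix[matrix.role == "control"].amplicons
    print(f"in-silico PCR: target {int(on.sum())}/{len(on)} amplify, "
          f"background {int(off.sum())}/{len(off)} amplify, control "
          f"{int((ctrl == 1).sum())}/{len(ctrl)} single-band")


if __name__ == "__main__":
    main()
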