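#!/usr/bin/env python
"""Generate the study family: a five-species simulated plastome set with
two accessions of the barcoding target and an IR-expanded outlier.

Writes sequence exports (GenBank/FASTA/alignment) to scratch/dataset/ and
the machine-readable truth tables to results/.
"""

from _common import RESULTS, SCRATCH, ensure_dirs, study_dataset

from plastomarker.simulate import export_dataset, truth_report


def main():
    ensure_dirs()
    ds = study_dataset()
    export_dataset(ds, SCRATCH / "dataset")
    truth_report(ds, RESULTS)
    print(f"simulated {len(ds.records)} plastomes "
          f"({next(iter(ds.records.values())).length} bp each, "
          f"alignment {ds.alignment.n_cols} columns)")
    print(f"reference accession: {ds.reference_id}")
    exp = ds.truth["partitions"]["P_maritima_01"].ir_length
    base = ds.truth["partitions"]["P_lanceolata_01"].ir_length
    print(f"IR expansion planted: P_maritima IR {exp} bp vs {base} bp "
          f"elsewhere")
    print(f"exports in {SCRATCH / 'dataset'}, truth tables in {RESULTS}")


if __name__ == "__main__":
    main()
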