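#!/usr/bin/env python
"""Frozen-fraction curves, cumulative IN spectra and onset/T50 summaries.

Reads the droplet CSVs written by 01_simulate_assays.py, runs the spectrum
estimator K(T) = ln(N0/N(T))/V with 95% Clopper-Pearson bounds, and reports
onset and median freezing temperatures per sample and treatment.

Outputs: results/spectra/spectrum_<sample>_<treatment>.tsv, results/summary.tsv
"""

from pathlib import Path

from dropfreeze import assay_spectrum, read_droplet_csv, summarize_assay
from dropfreeze.io import write_spectrum_tsv, write_summary_tsv

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    spectra_dir = RESULTS / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    summaries = []
    for csv_path in sorted(RESULTS.glob("droplets_*.csv")):
        for assay in read_droplet_csv(csv_path):
            spec = assay_spectrum(assay)
            write_spectrum_tsv(
                spec, spectra_dir / f"spectrum_{assay.sample_id}_{assay.treatment}.tsv"
            )
            s = summarize_assay(assay)
            summaries.append(s)
            t50 = f"{s.t50:.1f}" if s.t50 is not None else "undefined"
            onset = f"{s.onset_temp:.1f}" if s.onset_temp is not None else "undefined"
            print(f"{s.sample_id:16s} {s.treatment:13s} onset {onset:>6s} degC, "
                  f"T50 {t50:>6s} degC ({s.n_frozen}/{s.n_total} frozen)")
    write_summary_tsv(summaries, RESULTS / "summary.tsv")
    print(f"\nwrote {len(summaries)} summaries -> results/summary.tsv")


if __name__ == "__main__":
    main()
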