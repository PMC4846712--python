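# Report CSV schemas

All cohort reports written by `wmhdrift.pipeline.run_full_pipeline` (and the
`wmhdrift run-all` command) are CSV files with the following columns.  An
`index.csv` lists every table with its row count.

## ground_truth.csv
`subject_id`, `true_baseline_ml`, `true_followup_ml`, `true_increased_ml`,
`true_disappeared_ml`, `true_unchanged_ml`, `true_net_ml`, `n_lesions`,
`change_types` — generator bookkeeping, volumes in ml.

## change_per_subject.csv
`subject_id`, `method` (independent | independent_bfc | subtraction),
`net_change_ml`, `increased_ml`, `disappeared_ml`, `unchanged_ml`,
`baseline_ml`, `followup_ml`; for `independent_bfc` additionally
`mask_jaccard_vs_nobfc_baseline`, `mask_jaccard_vs_nobfc_followup`.

## method_per_subject.csv
`subject_id` plus one net-change column (ml) per method — the paired table.

## method_summary.csv
`method`, `median_ml`, `iqr_ml`, `n`.

## method_wilcoxon.csv
`method_a`, `method_b`, `w_plus` (positive-rank sum), `p` (two-sided).

## level_agreement.csv
Per-level rows: `subject_id`, `timepoint`, `level` (4 or 5), `jaccard`,
`vol_nobfc_pcticv`, `vol_bfc_pcticv`, `mean_pcticv`, `diff_pcticv` — the
points of the modified Bland-Altman agreement plot (x = uncorrected level
volume, y = Jaccard).  Change rows (`timepoint = change`, `level = 45`):
`bfc` (nobfc | bfc), `changed_pcticv`, `unchanged_pcticv`.

## vmr_medians.csv
`modality`, `timepoint`, `method`, `regime` (raw | icv | icv_nostroke),
`median_delta_vmr`, `iqr_delta_vmr`, `n`.

## vmr_ranking.csv
`method`, `median_abs_delta_vmr`, `rank` (1 = least distortion).

## ratings_synthetic.csv
`subject_id`, `fazekas_pv_baseline`, `fazekas_deep_baseline`,
`fazekas_pv_followup`, `fazekas_deep_followup`, `prins_total`, and one
`prins_sector_<name>` column per geometric sector (−1/0/+1).  Sectors are
geometry, not anatomy.

## correlations.csv
`method`, `against` (prins_total | age_synthetic), `correlation`
(spearman | pearson), `outliers_removed`, `coefficient`, `ci_low`,
`ci_high`, `p`, `n`, `note` (reason when a cell is not computable).  The
age covariate is synthetic, generated with a configurable true correlation
to the true change.
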