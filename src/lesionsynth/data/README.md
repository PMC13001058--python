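# Packaged study-findings corpus

`studies.tsv` and `findings.tsv` encode the literature-extraction table of
neuroimaging findings from OCD lesioning studies (24 studies, 443 treated
patients): per-study sample size, procedure, lesion and imaging modalities,
a mixed-cohort flag, and per-finding ROI references with measure and
direction of change.

Caveats:

- The `ybocs_pre_mean` / `ybocs_post_mean` columns are **synthetic**
  plausible cohort means, present for the 14 synthesis-eligible studies that
  reported group-level scores. The source tables do not print cohort Y-BOCS
  values, so outcome maps and Kruskal–Wallis results computed from this
  corpus are demonstrative, not a replication.
- ROI references use the package's curated lateralized parcel vocabulary
  (`roi_labels.tsv`, namespaces HO-Cort / HO-Sub / JHU / Cerebellum with
  package-assigned label ids). Unlateralized or "bilateral" structure
  mentions were expanded to both hemisphere parcels; medial and lateral
  orbitofrontal mentions were collapsed to one OFC parcel per hemisphere.
- `lexicon.tsv` maps free-text structure names (including common
  abbreviations) to parcels; it is data, so curated assignments stay
  auditable and editable.

Schema (tab-separated, one header row):

- `studies.tsv`: study_id, citation, n_treated, procedure, lesion_modality,
  imaging_modalities (semicolon-joined), mixed_cohort, ybocs_pre_mean,
  ybocs_post_mean (last two may be empty, only together).
- `findings.tsv`: finding_id, study_id, phase, atlas, label_id, hemisphere,
  measure, direction (-1 / 1 / NA), description. One ROI per row; rows of a
  multi-ROI finding share a finding_id.
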