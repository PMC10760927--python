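# Methods

## Scope and intent

`rdstage` derives a registry-level best estimate of AJCC 8th-edition TNM
stage at diagnosis for pancreatic carcinoma from multi-source registry
evidence, and provides the completeness and concordance analyses used to
evaluate such derivation rules. It is an epidemiological tool: the
derived stage supports population analyses and is not a clinical staging
of an individual patient. Free-text extraction (e.g. inferring
resectability from imaging report prose) is out of scope; resectability
is accepted only as an already-coded input.

## Eligibility

A whitelist: 19 ICD-O-3 carcinoma morphologies (behaviour /3 only)
crossed with the 7 pancreatic topography codes. Neuroendocrine tumours
are excluded simply by not being listed — they are staged on a different
system — so no NET blacklist exists and no NET-specific audit trail can
be produced. Behaviours other than /3 are ineligible even for listed
morphologies (the rules target invasive carcinoma). The code tables ship
as versioned two-column text files (`src/rdstage/data/*.tsv`) so they can
be audited and replaced per registry without code changes; `--vocab-dir`
swaps them at run time.

## Evidence window

Evidence is admissible from 30 days before diagnosis (configurable slack
— registries time-stamp "diagnosis" heterogeneously, and work-up imaging
legitimately precedes it) to 120 days after (inclusive boundary: "within
120 days"), and strictly before the first treatment date (exclusive
boundary: "before primary cancer treatment"). Both inclusivities are
documented choices, configurable via `StagingWindow`. Undated records are
never admissible.

## Category derivation

Order is M, then N, then T: confirmed distant metastasis is stage IV and
makes N/T moot (they are reported as NX/TX with no provenance rather than
derived).

**M.** M1 evidence: explicit M1 statement from any tier; an ICD-10-AM
C77–C79 code on an admitted episode; metastatic-unresectable
resectability; a death-certificate metastasis flag. C77 (secondary
lymph-node disease) counts as distant by default, matching registry use
of the whole block to flag metastatic disease; `M0Policy(c77_is_distant=
False)` treats C77 as regional (AJCC would call regional-node secondaries
N-disease, not M1). An explicit M0 statement gives M0-evidenced.
Otherwise the policy decides:

- `ASSUME_M0` (default): M0 assumed — the AJCC cM0 convention that a
  patient is clinically M0 unless there is evidence otherwise.
- `QUEENSLAND`: M0 only if the patient had an admission more than
  `lookback_days` (default 120) after diagnosis that was free of
  metastatic-site codes; otherwise M is unresolved and the stage Unknown.
  As a safety property, a C77–C79 coded admission at *any* date forbids
  M0 under this policy, even against an explicit in-window M0 statement:
  the policy exists precisely because assumed M0s were judged unsafe, so
  the engine prefers Unknown over a contradicted M0.

**N.** Explicit statement from the most trusted tier wins; else regional
node counts: 0 positive → N0 only when at least one node was examined
(an unexamined zero is no information), 1–3 → N1, ≥ 4 → N2; else NX.

**T.** Explicit statement wins (T1a/b/c collapse to T1 — registries
rarely receive sub-category detail and the prognostic groups do not use
it; Tis is excluded since in-situ behaviour is ineligible). Else arterial
involvement defines T4 irrespective of any recorded size (the size is
logged as overridden); else size with closed upper bounds: ≤ 20 mm T1,
≤ 40 mm T2, > 40 mm T3; else TX.

**Conflicts** between tiers resolve by tier rank (MDT 1, pathology 2,
oncology system 3, admissions 4, imaging 5), not recency — mirroring the
clinical-advisory hierarchy that ranks MDT consensus above individual
reports; within a tier, earlier records win, with a stable textual
tiebreak so derivation is invariant to evidence order. Death certificates
sit outside the hierarchy and are consulted for metastasis evidence only.

## Stage grouping and unknowns

The prognostic-group table (IA T1N0, IB T2N0, IIA T3N0, IIB T1–3 N1,
III N2 any-T or T4 any-N, IV M1) is extended to a total function on the
5×4×4 (T, N, M) lattice: M1 dominates for all T and N; unresolved M gives
Unknown; with M0, X categories are enumerated over their consistent
resolutions and a group is reported only when all resolutions agree.
This makes staging conservative by construction — removing evidence can
move a case to Unknown but never to a different stage — which the test
suite verifies both exhaustively (80-point lattice against an independent
enumeration oracle) and statistically (degraded synthetic extracts).
M0-evidenced and M0-assumed are distinguished in provenance but stage
identically.

An explicit stage-group statement (e.g. an MDT "IIB") is used only when
no component T/N/M evidence produced a category, so any derivable stage
remains auditable back to components; whether a stated MDT stage should
override contradictory pathology is genuinely open, and this rule is the
package's documented choice. A statement at collapsed level ("stage 2")
fills the collapsed stage but leaves the sub-group Unknown. Cases flagged
neoadjuvant whose pathology all post-dates treatment are a terminal
post-neoadjuvant state, never mapped to I–IV (post-treatment pathology no
longer reflects stage at diagnosis, and ypTNM restaging is out of scope).

## Completeness reporting

A field counts as available for a case if *any* in-window evidence record
populates it, regardless of tier — availability, not best-source
availability. Stage assignability is different: it reruns the full engine
on evidence restricted to a chosen tier set, so it reflects what the
rules can actually do with those sources (and is provably monotone in the
tier set). Post-neoadjuvant counts separately, not as staged. Degree of
spread (the summary-stage ordinal some jurisdictions collect instead of
TNM) is carried as a pass-through case field for completeness counting
only; deriving it is out of scope. Jurisdiction is a grouping column, not
a type; `completeness_table(..., group_by="jurisdiction")` emits one
column per group.

## Concordance statistics

Pairs are formed by exact-identifier inner join (duplicate identifiers
are an error; probabilistic linkage is out of scope). The 4×4
cross-tabulation covers stages I–IV; Unknown or post-neoadjuvant on
either side excludes a pair from comparison but is tallied. Percent
agreement is trace over total, displayed to one decimal as a percentage.

The ordinal agreement statistic is reported under two variants, both
tie-corrected: the Kendall rank correlation τ_b (default) and Kendall's
coefficient of concordance W for two raters. On the bundled 229-pair
validation fixture τ_b = 0.92 while W = 0.97; published two-rater stage
agreement labelled "Kendall's coefficient of concordance" is ambiguous
between the two, and τ_b is the variant that reproduces the published
value, so it is the documented default. Significance uses a seeded
permutation test (default 10,000 permutations of one margin) rather than
the asymptotic chi-square null, which is unreliable under the heavy ties
of a stage-IV-dominated distribution.

The fixture (`data/validation_pairs.csv`) is reconstructed from a
published validation cross-tabulation's cell counts (rows 15,1,0,1 /
0,16,4,0 / 2,0,8,0 / 2,0,1,179); pair-level order is unrecoverable and
irrelevant — every statistic here is permutation-invariant, which is
itself tested.

## Synthetic registry generator

The generator draws a true prognostic group per case, synthesises
internally consistent ground-truth TNM, then emits evidence thinned by a
per-field completeness profile and per-tier availability. Defaults are
chosen to emulate the study conditions the package is built around:

- **Stage distribution**: shaped on the staged portion of a Victorian
  extract (I 25, II 26, III 19, IV 213 of 283), sub-splits IA/IB and
  IIA/IIB even, since registries report collapsed stage.
- **Completeness profiles**: `VICTORIA_PROFILE` and `QUEENSLAND_PROFILE`
  carry the respective jurisdictions' observed per-field availability;
  `FULL_PROFILE` is the no-missingness control. Victoria is the default.
- **`m1_admission_coding_rate` = 0.62**: with ~75% of cases truly
  metastatic this yields ~47% of all cases carrying a coded metastatic
  admission, the observed jurisdictional rate.
- **`neoadjuvant_rate` = 9/457**, the validation-cohort proportion.
- **`late_admission_rate` = 0.6**: fraction of non-metastatic cases with
  a metastasis-free admission beyond 120 days (exercises the strict M0
  policy); a plausibility choice, not an observed figure.
- **Truth bands**: T sizes uniform within the generating band (T1 5–20,
  T2 21–40, T3 41–80 mm), N1 1–3 and N2 4–12 positive of 8–24 examined
  nodes — arbitrary but documented.
- **Reference-registry emulation**: the discordance model keeps the true
  collapsed stage except for seeded perturbations (±1 stage with rate
  11/229, Unknown with rate 189/457, both shaped on the validation
  cohort).

Two deliberate consistency constraints make the conservatism property
provable rather than approximate: metastatic cases carry no tumour/node
evidence (distant disease makes local work-up moot — losing all
metastasis evidence therefore degrades to Unknown, or exposes the known
falsely-assumed-M0 hazard of the default policy, never a partially wrong
stage), and T4 cases carry arterial involvement but no size (a bare size
would downgrade to T3 if the involvement were thinned away).

What the generator does **not** emulate: real missingness is not
independent per field (a missing pathology report removes all its fields
at once — tier availability captures some of this, per-field thinning the
rest), diagnosis dates carry no seasonality, no demographics or survival,
no transcription errors in codes, and reference-registry errors are
symmetric ±1 steps. Passing round-trip and conservatism tests therefore
shows the rules are correct and never-guessing on consistent evidence; it
does not certify accuracy on real extracts, where contradictory evidence
between sources (resolved here by tier rank) is the dominant hazard.

## Numerical and engineering choices

Proportions are kept at full precision and rounded only for display
(percent agreement to one decimal). Probability vectors must sum to 1
within 1e-9. Permutation p-values use the add-one estimator
(hits+1)/(m+1). Row-level input validation collects problems with row
numbers instead of failing the read; orphan evidence is dropped with a
warning. Every CLI run writes a manifest (tool and vocabulary versions,
parameters, SHA-256 input digests) beside its output, and identical
inputs yield byte-identical outputs. Problem sizes in the shipped
analyses (2,000-case round-trip, 1,000-case degradation, 10,000
permutations) were chosen so each statistical check has negligible Monte
Carlo error at three binomial standard deviations.

## Known limitations

- Confidential jurisdictional results (completeness percentages, M1
  proportions, unknown-stage counts) cannot be recomputed from real data
  here; they exist only as generator profiles, and tests check extracts
  against the *configured* profile within binomial tolerance, never
  against the published figures.
- Of the 457-pair validation cohort, only the 229-pair both-staged
  sub-population is reconstructable from published counts; the overlap
  structure of the unknown/post-neoadjuvant margins is not, so
  margin-level behaviour is exercised on synthetic constructions.
- "Date of diagnosis" is taken as given input; its operational definition
  (pathology date vs first clinical suspicion) varies by registry.
- The engine implements the published main rules plus the AJCC
  8th-edition tables; coder-workflow aids (follow-up prompts,
  treatment-pathway diagrams) that accompany the manual rules are not
  modelled.
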