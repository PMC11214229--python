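# tierstage

Tiered derivation of AJCC TNM stage at diagnosis from heterogeneous
cancer-registry sources.

Population-based cancer registries rarely hold a single clean record of a
patient's stage at diagnosis. What they do hold is fragmentary: explicit
prefixed TNM values in pathology reports (`pT1 pNX pMX`), coded hospital
admissions (ICD-10 secondary-malignancy codes), and — for a minority of
cases — full clinical/MDT staging (`cT1 cN2 cM1a`). `tierstage` turns those
fragments into an AJCC 8th-edition **anatomic stage group** for every case
and, crucially, labels each result with a **completeness tier** so analysts
know what the number can be used for:

| Tier | Name | Meaning |
|------|------|---------|
| 1 | Complete AJCC TNM | Sub-stage-level stage from clinical-grade data; fit for clinical and epidemiological use |
| 2 | RD-Stage (registry-derived) | Stage derivable only with admission-code supplementation and/or absence assumptions; epidemiological use |
| 3 | Pathology Stage | pTNM from pathology reports alone; minimum-insight epidemiological use, under-staging risk |
| — | Unstageable | No stage group derivable from any in-window source |

The package is aimed at registry engineers and cancer epidemiologists who
need reproducible, auditable stage-derivation business rules — and a way to
test them without patient data.

## The rules in brief

For each case, writing T, N, M for the tumour/node/metastasis categories
with prefixes p (pathological), c (clinical) and y (post-therapy):

1. **Window.** Only records with 0 ≤ (record date − diagnosis date) ≤ 120
   days contribute (inclusive both ends; configurable).
2. **Supplementation.** In-window admission codes are mapped to binary
   evidence: any nodal code (default C77\*) ⇒ N = 1, any secondary-malignancy
   code (default C78\*/C79\*) ⇒ M = 1. Binary values never carry
   subcategories.
3. **Conflict resolution.** Per axis, the more advanced value wins
   (NX < N0 < N1 < N1a < … ; X always loses to a stated value); exact ties
   break to the more specific value, then clinical > pathology > admission,
   then the earliest record. y-prefixed values are excluded from
   stage-at-diagnosis derivation by default.
4. **Absence assumptions.** Missing or X-valued N and M become N0/M0
   (recorded as assumptions; T is never assumed).
5. **Grouping.** The final (T, N, M) is mapped through the site's AJCC 8e
   stage table (colorectal, breast anatomic, melanoma with separate
   clinical/pathological grouping). Values lacking the subcategory detail
   needed for a unique sub-stage fall back to the main **umbrella** stage
   (e.g. IIIA → III); admission-sourced axes always force the umbrella.
6. **Tiering.** Tier 1 requires a sub-stage-level result with every axis
   explicit or a corroborated absence (admission stream reviewed and
   silent); Tier 3 means only pathology contributed; everything else
   stageable is Tier 2.

Stage tables ship as human-reviewable text assets
(`src/tierstage/data/*.tsv`) and are exhaustively integrity-checked at load:
every valid (T, N, M) combination matches exactly one row.

## Worked example

Three colorectal cases diagnosed 2019-03-01 — a pathology report carrying
clinical M, a report with unassessable N/M plus a nodal admission code, and
a subcategoried report with no other sources:

`pathology.csv`
```csv
case_id,diagnosis_date,site,tnm_string
case-001,2019-03-01,colorectal,pT1N2 cM1a
case-002,2019-03-01,colorectal,pT1 pNX pMX
case-003,2019-03-01,colorectal,pT1 pN2a pMX
```

`admissions.csv`
```csv
case_id,admission_date,codes
case-002,2019-04-01,C77.9;K56.6
```

```sh
tierstage run --pathology pathology.csv --admissions admissions.csv --out out
```

`out/staged.csv`:

```csv
case_id,site,t,n,m,stage_group,umbrella_only,tier,assumptions,t_source,n_source,m_source,post_therapy,reason
case-001,colorectal,pT1,pN2,cM1a,IVA,False,1,,pathology,pathology,pathology,False,
case-002,colorectal,pT1,N1,M0,III,True,2,MX->M0,pathology,admission,assumption,False,
case-003,colorectal,pT1,pN2a,M0,IIIA,False,3,MX->M0,pathology,pathology,assumption,False,
```

Reading the rows: case-001 has complete TNM (the pathologist transferred
the clinical M1a), so it stages IVA at Tier 1. case-002's nodal involvement
is known only as a binary admission code, so the stage is the umbrella III —
not IIIA — at Tier 2, with the MX→M0 assumption recorded. case-003 derives
the same TNM as a Tier-1 case would, but with nothing beyond the pathology
report to corroborate it, it is Tier 3. The run also writes a tier-profile
report (`out/report.txt`) with one `n (%)` column per site.

## Synthetic registries

```sh
tierstage simulate --preset colorectal-like --n 1000 --seed 42 --out sim/
tierstage run --pathology sim/pathology.csv --admissions sim/admissions.csv \
              --clinical sim/clinical.csv --out sim-out/
```

`simulate` writes the three linked input tables plus `ground_truth.csv`
(true sub-stage TNM per case), generated under configurable per-source
availability, per-site true-stage distributions and a neoadjuvant-therapy
fraction. Identical spec + seed gives byte-identical output. See
`docs/methods.md` for what the generator does and does not emulate.

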