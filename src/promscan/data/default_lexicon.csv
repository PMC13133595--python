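instrument_id,canonical_name,acronyms,kind,condition_tag
I001,European Organisation for Research and Treatment of Cancer Quality of Life Questionnaire-Core 30,EORTC QLQ-C30;QLQ-C30,PROM,cancer
I002,Functional Assessment of Cancer Therapy - General,FACT-G,PROM,cancer
I003,Cancer-Related Quality of Life Scale,Cancer-Related QoL,PROM,cancer
I004,Hospital Anxiety and Depression Scale,HADS,PROM,mental health
I005,Cancer Visual Analogue Scale,C-VAS,PROM,cancer
I006,National Cancer Institute Patient Symptom Inventory,NCI,PROM,cancer
I007,EuroQol 5-Dimension 5-Level,EQ-5D-5L,PROM,generic
I008,Patient-Reported Outcomes version of the Common Terminology Criteria for Adverse Events,PRO-CTCAE,PROM,cancer
I009,International Prostate Symptom Score,IPSS,PROM,prostate
I010,EuroQol 5-Dimension 3-Level,EQ-5D-3L,PROM,generic
I011,Short Form 36 Health Survey,SF-36,PROM,generic
I012,Fatigue Severity Scale,FSS,PROM,fatigue
I013,European Organisation for Research and Treatment of Cancer Quality of Life Questionnaire-Lung Cancer 13,EORTC QLQ-LC13;QLQ-LC13,PROM,lung
I014,European Organisation for Research and Treatment of Cancer Quality of Life Questionnaire-Head and Neck 35,EORTC QLQ-H&N35;QLQ-H&N35,PROM,head and neck
I015,European Organisation for Research and Treatment of Cancer Quality of Life Questionnaire-Breast 23,EORTC QLQ-BR23;QLQ-BR23,PROM,breast
I016,Functional Assessment of Cancer Therapy - Breast,FACT-B,PROM,breast
I017,Functional Assessment of Cancer Therapy - Lung,FACT-L,PROM,lung
I018,Functional Assessment of Cancer Therapy - Prostate,FACT-P,PROM,prostate
I019,Functional Assessment of Chronic Illness Therapy - Fatigue,FACIT-Fatigue,PROM,fatigue
I020,Brief Pain Inventory,BPI,PROM,pain
I021,MD Anderson Symptom Inventory,MDASI,PROM,cancer
I022,Edmonton Symptom Assessment System,ESAS,PROM,cancer
I023,Patient Health Questionnaire-9,PHQ-9,PROM,depression
I024,Generalized Anxiety Disorder 7-item scale,GAD-7,PROM,anxiety
I025,Expanded Prostate Cancer Index Composite,EPIC-26,PROM,prostate
I026,International Index of Erectile Function,IIEF,PROM,urogenital
I027,Functional Assessment of Cancer Therapy - Colorectal,FACT-C,PROM,digestive
I028,European Organisation for Research and Treatment of Cancer Quality of Life Questionnaire-Colorectal 29,EORTC QLQ-CR29;QLQ-CR29,PROM,digestive
I029,Multidimensional Fatigue Inventory,MFI-20,PROM,fatigue
I030,Rotterdam Symptom Checklist,RSCL,PROM,cancer
I031,Memorial Symptom Assessment Scale,MSAS,PROM,cancer
I032,Beck Depression Inventory,BDI-II,PROM,depression
I033,Insomnia Severity Index,ISI,PROM,sleep
I034,Pittsburgh Sleep Quality Index,PSQI,PROM,sleep
I035,Patient-Reported Outcomes Measurement Information System Global Health,PROMIS Global Health,PROM,generic
I036,European Organisation for Research and Treatment of Cancer Quality of Life Questionnaire-Prostate 25,EORTC QLQ-PR25;QLQ-PR25,PROM,prostate
I037,Consumer Assessment of Healthcare Providers and Systems,CAHPS,PREM,care experience
I038,Picker Patient Experience Questionnaire,PPE-15,PREM,care experience
I039,Patient Satisfaction Questionnaire Short Form,PSQ-18,PREM,care experience
I040,EORTC Cancer Outpatient Satisfaction with Care Questionnaire,EORTC IN-PATSAT32;IN-PATSAT32,PREM,cancer care
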