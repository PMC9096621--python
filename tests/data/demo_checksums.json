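{
  "annotation.gff3": "15d457d30e9a00fa5ed776b7825c94048897bb08accb2547055445634d5fd823",
  "cluster_de.tsv": "798179dd28da09008deacbaa6b0b04af467fae3eecadab82e0da9398ff33d81d",
  "cluster_dm.tsv": "669c1975a04268243ab7c257d7308279e52a165b9e20046adf753adcd581a8df",
  "clusters.bed": "86d0e1b17af18bf8dd6d3514d2a0a54a53a41d68e0617a7d34e0d6d28f1c78b5",
  "clusters.tsv": "08236a3b10ccac32cd0316e35deb3a5006cf09d83be6772802654cbf0b9c3919",
  "cytosines_WT.tsv": "bbcdc23054a9d28bc4db50904edeb6accd33f1388d6025e91616e81025f60999",
  "cytosines_mut.tsv": "592acd3f9418035671464ebe06263da00afb102742673173da87b11582877512",
  "de_genes.tsv": "34d11882b1080ac73b2bb7fcc6d67f2468bfafc85e1fe15875289e5a00a944d5",
  "dm_promoters.bed": "1af1a0d56bebaf827718cc6294912942679b4419b1fdcc3acb84ce5d6fca0df5",
  "dm_promoters.tsv": "ee5ca07574afb50f355c9170de608eaaf2052bf7b96dd47361aff4bd494b542a",
  "gene_counts.tsv": "2fb5d16f6304272516eeb431e88fa4d7835e2f42cbec575294db9b6848740001",
  "genome.fa": "c52f9d93740a262f795a7067286e3f333915d2cfd6cdad086aae375d8f9ecfe1",
  "integration_per_gene.tsv": "afe81c9312916919db74fcfaa12bcd66d329c67d769db7eef0bac824b5db57d1",
  "integration_srna_strata.tsv": "5b85e7cd6e791dcbe256d180960fbe8d3541d39e99ec5034759fd7b3b8b47945",
  "integration_summary.json": "36df69aebd8fe2227b527ac38f89c89e4f617f7fe661d4932f386e58c29a00b3",
  "motif.pfm": "537806b288655708aff85a1766fd8f4940fdca48ae8010c5df795ba7f74b3291",
  "motif_curves_DEMO_PIF.tsv": "0c49c98926b62792bb144444f068616f32867502b538a39793919376716a1688",
  "motif_enrichment.json": "a782a4c326da73901d206ea8c7643d61576618076fb8524303aaff4e5817454c",
  "motif_hits.tsv": "442c2b91262f6b0c20694815fe15db2a092743f8063b56ba11459c1c198b2edd",
  "srna_reads_WT_1.bed": "aa72938345343dddd42b5f20f28cf3cd9222b3541729109e8ebc7caab226b71d",
  "srna_reads_WT_2.bed": "a8cdc5140fd5ac94b8768c334fcd018279429f5085b70aafbb68f66015fd5ae0",
  "srna_reads_WT_3.bed": "0a640b2622a7379c327a55ed3e1d33b24db5ef548f8f96488ed0e153657d795c",
  "srna_reads_mut_1.bed": "da35d8752926da0de272f416dd567bde5ebaab8540e3dffe48287e1f55cb806e",
  "srna_reads_mut_2.bed": "1f06112c84ce02bc7ea7cf7f340735ca0d9a3dec5e02e92165d24e8b74d9ed42",
  "srna_reads_mut_3.bed": "31a74137b6b2dcb01ceefd2e1a3c17d8d3a0be85b785db604b482dfaac38b748"
}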