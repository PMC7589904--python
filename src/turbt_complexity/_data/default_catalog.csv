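item_id,domain,label,median_opinion,weight
hist_none,history,No relevant history,1,1
hist_hip_surgery,history,Hip surgery,2,2
hist_radical_prostatectomy,history,Radical prostatectomy,2,2
hist_repeated_turbt,history,Repeated TURBT (>3),2,2
hist_bladder_perforation,history,Prior bladder perforation,2,2
hist_mmc_bcg,history,MMC or BCG instillations,2,2
hist_uti,history,Urinary tract infection,2,2
hist_obese,history,Obese (BMI > 30),3,3
hist_pelvic_radiation,history,Pelvic radiation,3,3
hist_open_bladder_surgery,history,Any open bladder surgery,3,3
hist_bleeding_disorder,history,Bleeding disorder or anticoagulant use,3,3
hist_asa_4_5,history,ASA class 4-5,4,4
acc_none,access,No relevant features,1,1
acc_large_bladder,access,Large bladder (>500 mL),2,2
acc_trabeculations,access,Irregular bladder wall or trabeculations,2,2
acc_urethral_stricture,access,Urethral stricture,3,3
acc_bladder_neck,access,High or narrow bladder neck,3,3
acc_median_lobe,access,Large median lobe,3,3
acc_large_prostate,access,Large prostate (60-90 mL),3,3
acc_small_bladder,access,Small bladder (100-250 mL),3,3
acc_prolapse,access,Female prolapse or cystocele,3,3
acc_no_lithotomy,access,Not amenable to lithotomy position,4,4
acc_very_small_bladder,access,Very small bladder (<100 mL),4,4
acc_very_large_prostate,access,Very large prostate (>90 mL),4,4
acc_bladder_hernia,access,Bladder hernia,4,4
acc_thin_wall,access,Thin bladder wall,4,4
num_1_3,number,1-3 tumours,1,1
num_4_10,number,4-10 tumours,3,3
num_gt10,number,>10 tumours,4,4
size_lt3,size,<3 cm,1,1
size_second_look,size,Recent TURBT (second look),2,2
size_3_5,size,3-5 cm,3,3
size_cis_area,size,Large micropapillary or CIS-suspicious area (>5 cm2),3,3
size_gt5,size,>5 cm,4,4
loc_trigon,location,Trigon,1,1.5
loc_prostatic_urethra,location,Prostatic urethra,2,3
loc_bladder_neck,location,Bladder neck,2,3
loc_lateral_wall,location,Lateral wall,2,3
loc_posterior_wall,location,Posterior wall,3,4.5
loc_anterior_wall,location,Anterior wall,3,4.5
loc_ureteric_orifice,location,Ureteric orifice,3,4.5
loc_dome,location,Dome,4,6
loc_obturator_jerk,location,Anticipate obturator jerk,4,6
loc_diverticulum,location,Diverticulum,4,6
struct_papillary,tumour_structure,Papillary pedunculated,2,
struct_sessile,tumour_structure,Sessile or flat,2,
struct_cis,tumour_structure,Carcinoma in situ,2,
struct_micropapillary,tumour_structure,Micropapillary area,3,
struct_necrotic,tumour_structure,Necrotic or bleeding tumour,3,
anat_normal,bladder_anatomy,Normal bladder anatomy,2,
anat_trabeculated,bladder_anatomy,Trabeculated bladder wall,3,
anat_diverticula,bladder_anatomy,Multiple diverticula,3,
anat_small_capacity,bladder_anatomy,Reduced bladder capacity,3,
anat_scarred,bladder_anatomy,Scarring from previous resections,3,
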