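domain,item_id,label,weight
history,hist_none,No relevant history,1
history,hist_hip_surgery,Hip surgery,2
history,hist_radical_prostatectomy,Radical prostatectomy,2
history,hist_repeated_turbt,Repeated TURBT (>3),2
history,hist_bladder_perforation,Prior bladder perforation,2
history,hist_mmc_bcg,MMC or BCG instillations,2
history,hist_uti,Urinary tract infection,2
history,hist_obese,Obese (BMI > 30),3
history,hist_pelvic_radiation,Pelvic radiation,3
history,hist_open_bladder_surgery,Any open bladder surgery,3
history,hist_bleeding_disorder,Bleeding disorder or anticoagulant use,3
history,hist_asa_4_5,ASA class 4-5,4
access,acc_none,No relevant features,1
access,acc_large_bladder,Large bladder (>500 mL),2
access,acc_trabeculations,Irregular bladder wall or trabeculations,2
access,acc_urethral_stricture,Urethral stricture,3
access,acc_bladder_neck,High or narrow bladder neck,3
access,acc_median_lobe,Large median lobe,3
access,acc_large_prostate,Large prostate (60-90 mL),3
access,acc_small_bladder,Small bladder (100-250 mL),3
access,acc_prolapse,Female prolapse or cystocele,3
access,acc_no_lithotomy,Not amenable to lithotomy position,4
access,acc_very_small_bladder,Very small bladder (<100 mL),4
access,acc_very_large_prostate,Very large prostate (>90 mL),4
access,acc_bladder_hernia,Bladder hernia,4
access,acc_thin_wall,Thin bladder wall,4
number,num_1_3,1-3 tumours,1
number,num_4_10,4-10 tumours,3
number,num_gt10,>10 tumours,4
size,size_lt3,<3 cm,1
size,size_second_look,Recent TURBT (second look),2
size,size_3_5,3-5 cm,3
size,size_cis_area,Large micropapillary or CIS-suspicious area (>5 cm2),3
size,size_gt5,>5 cm,4
location,loc_trigon,Trigon,1.5
location,loc_prostatic_urethra,Prostatic urethra,3
location,loc_bladder_neck,Bladder neck,3
location,loc_lateral_wall,Lateral wall,3
location,loc_posterior_wall,Posterior wall,4.5
location,loc_anterior_wall,Anterior wall,4.5
location,loc_ureteric_orifice,Ureteric orifice,4.5
location,loc_dome,Dome,6
location,loc_obturator_jerk,Anticipate obturator jerk,6
location,loc_diverticulum,Diverticulum,6
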