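target,source,S_mGy_per_MBq_s,phantom
kidneys,kidneys,3.2000e-05,adult_male
kidneys,liver,6.0000e-07,adult_male
kidneys,lungs,1.5000e-07,adult_male
kidneys,urinary_bladder,2.0000e-07,adult_male
kidneys,gall_bladder,5.0000e-07,adult_male
kidneys,rest_of_body,8.0000e-07,adult_male
liver,kidneys,6.0000e-07,adult_male
liver,liver,6.0000e-06,adult_male
liver,lungs,4.0000e-07,adult_male
liver,urinary_bladder,8.0000e-08,adult_male
liver,gall_bladder,1.2000e-06,adult_male
liver,rest_of_body,8.0000e-07,adult_male
lungs,kidneys,1.5000e-07,adult_male
lungs,liver,4.0000e-07,adult_male
lungs,lungs,8.0000e-06,adult_male
lungs,urinary_bladder,2.0000e-08,adult_male
lungs,gall_bladder,2.5000e-07,adult_male
lungs,rest_of_body,8.0000e-07,adult_male
urinary_bladder_wall,kidneys,2.0000e-07,adult_male
urinary_bladder_wall,liver,8.0000e-08,adult_male
urinary_bladder_wall,lungs,2.0000e-08,adult_male
urinary_bladder_wall,urinary_bladder,2.8000e-05,adult_male
urinary_bladder_wall,gall_bladder,6.0000e-08,adult_male
urinary_bladder_wall,rest_of_body,8.0000e-07,adult_male
gall_bladder_wall,kidneys,5.0000e-07,adult_male
gall_bladder_wall,liver,1.2000e-06,adult_male
gall_bladder_wall,lungs,2.5000e-07,adult_male
gall_bladder_wall,urinary_bladder,6.0000e-08,adult_male
gall_bladder_wall,gall_bladder,2.5000e-05,adult_male
gall_bladder_wall,rest_of_body,8.0000e-07,adult_male
rest_of_body,kidneys,8.0000e-07,adult_male
rest_of_body,liver,8.0000e-07,adult_male
rest_of_body,lungs,8.0000e-07,adult_male
rest_of_body,urinary_bladder,8.0000e-07,adult_male
rest_of_body,gall_bladder,8.0000e-07,adult_male
rest_of_body,rest_of_body,1.5000e-06,adult_male
kidneys,kidneys,3.5200e-05,adult_female
kidneys,liver,6.6000e-07,adult_female
kidneys,lungs,1.6500e-07,adult_female
kidneys,urinary_bladder,2.2000e-07,adult_female
kidneys,gall_bladder,5.5000e-07,adult_female
kidneys,rest_of_body,8.8000e-07,adult_female
liver,kidneys,6.6000e-07,adult_female
liver,liver,6.6000e-06,adult_female
liver,lungs,4.4000e-07,adult_female
liver,urinary_bladder,8.8000e-08,adult_female
liver,gall_bladder,1.3200e-06,adult_female
liver,rest_of_body,8.8000e-07,adult_female
lungs,kidneys,1.6500e-07,adult_female
lungs,liver,4.4000e-07,adult_female
lungs,lungs,8.8000e-06,adult_female
lungs,urinary_bladder,2.2000e-08,adult_female
lungs,gall_bladder,2.7500e-07,adult_female
lungs,rest_of_body,8.8000e-07,adult_female
urinary_bladder_wall,kidneys,2.2000e-07,adult_female
urinary_bladder_wall,liver,8.8000e-08,adult_female
urinary_bladder_wall,lungs,2.2000e-08,adult_female
urinary_bladder_wall,urinary_bladder,3.0800e-05,adult_female
urinary_bladder_wall,gall_bladder,6.6000e-08,adult_female
urinary_bladder_wall,rest_of_body,8.8000e-07,adult_female
gall_bladder_wall,kidneys,5.5000e-07,adult_female
gall_bladder_wall,liver,1.3200e-06,adult_female
gall_bladder_wall,lungs,2.7500e-07,adult_female
gall_bladder_wall,urinary_bladder,6.6000e-08,adult_female
gall_bladder_wall,gall_bladder,2.7500e-05,adult_female
gall_bladder_wall,rest_of_body,8.8000e-07,adult_female
rest_of_body,kidneys,8.8000e-07,adult_female
rest_of_body,liver,8.8000e-07,adult_female
rest_of_body,lungs,8.8000e-07,adult_female
rest_of_body,urinary_bladder,8.8000e-07,adult_female
rest_of_body,gall_bladder,8.8000e-07,adult_female
rest_of_body,rest_of_body,1.6500e-06,adult_female
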